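# Methods

This note documents the models, numerical choices and limitations of
`te-longsel`: what each analysis assumes, what the synthetic data do and do
not emulate, and where the design was genuinely open.

## Data surfaces and conventions

Two in-memory structures carry everything:

* **CoverageProfile** — one value per (TE family, population, consensus
  position): the normalized insertion estimate at that position, i.e.
  TE read depth divided by single-copy-gene depth.  Averaging a family's
  positions gives its mean insertions per haploid genome.
* **InsertionSiteTable** — genomic insertion sites (chromosome, 1-based
  position, family) with one frequency column per population; a site not
  detected in a population is an explicit `NA` and is excluded from any
  test requiring that population.  Pool-seq insertion calling is
  coverage-dependent, so absence of evidence is treated as missingness,
  not as frequency zero.

All coordinates in the package are 1-based and inclusive
(`io_formats.COORDINATE_BASE`).  Tables are UTF-8 TSV; floats are written
with 6 significant digits and rows in deterministic sorted order, so
reruns are byte-identical.

## Abundance classification

**Retention filter.**  A family enters the analysis only if, averaging
across all populations of a study at each consensus position, at least 80%
of positions have ≥ 0.5 insertions.  Both bounds are inclusive; a family
sitting exactly at 80% is retained.  This removes families whose coverage
is too low or too patchy for copy-number estimates to mean anything.

**Approach #1 (per-study ANOVA).**  Per retained family, per-position
values are modelled with sequential (type-I) sums of squares in the order
`Regime, Population` (replicates nested in regime via globally unique
population labels) or `Regime, Diet, Regime:Diet` for diet-crossed
designs, every term tested against the residual mean square — the default
behaviour of R's `aov`, which is the idiom this pipeline reproduces.  Note
the deliberate pseudoreplication: positions within a population are
treated as independent observations, exactly as the source idiom does, so
the p-values are anti-conservative in an absolute sense and meaningful
mainly under the Bonferroni-plus-effect-filter combination that follows.
A family is labelled S>C or C>S only when the regime term passes
Bonferroni at α = 0.01 across the study's retained families *and* the
regime means differ by more than 0.3 insertions (δ<sub>insertion</sub>,
strictly greater).  The Bonferroni divisor is the per-study retained
count, not a pooled cross-study count.

**Approach #2 (cross-study proportions).**  Only families retained in
every study are analysed.  The response is asin(√(family copies / total
TE copies in that population)) — the arcsine square root stabilises the
variance of proportions — with terms `Study, Regime, Study:Regime` and
BH-FDR < 0.05 on the regime term.  Direction comes from the pooled regime
means of the transformed proportion.

**Approach #3 (consistency).**  No test: a family is S>C iff the smallest
selected value strictly exceeds the largest control value, and C>S in the
mirror case.  "Consistent" is read as all-pairwise dominance because the
alternative (paired replicates) is ill-defined for unequal replicate
counts.  For diet-crossed designs the call is made within each diet.

Fold changes are log₂(mean_S / mean_C) with no pseudo-count — the
retention filter keeps regime means away from zero, and a nonpositive mean
surfaces as NaN rather than a silently shifted value.

Group contrasts (|log₂FC| between the C>S and S>C groups, |δ| likewise,
and the study-wise ANOVA of |log₂FC|) use Welch t-tests; the post-hoc
comparison between studies uses pairwise Welch tests with Holm adjustment
in place of Tukey's studentized-range HSD.  Holm controls the same
family-wise error rate; only qualitative orderings are drawn from it.

## Frequency analytics

Mean segregating frequency per family and population averages the
frequencies of its detected (non-NA) sites, equally weighted (site-level
precision weights are not available from the emulated surface).  Per-site
and per-family regime tests run on arcsine-square-root transformed
frequencies: per site the model is `Regime` alone (or
`Diet, Regime, Diet:Regime`), Bonferroni-controlled at α = 0.05 over the
number of sites actually tested — sites observed in fewer than two
populations per regime are skipped and do not enter the divisor.  The
per-family test pools all site × population values as independent
observations (again the source idiom; no site random effect) with
BH-FDR < 0.05 across families.

Gene annotation uses a 1000-bp window measured from gene start/end
coordinates (UTRs are not modelled), inclusive at exactly 1000 bp; inside
means start ≤ pos ≤ end; upstream/downstream are resolved by gene strand;
among multiple qualifying genes the nearest wins, exact ties going to the
lexicographically smallest gene id.

## The drift null

Each family's abundance proxy starts at its reference mean frequency p₀
and every replicate evolves independently as a Wright–Fisher binomial:
p ← Binomial(2Nₑ, p) / 2Nₑ per generation, 0 and 1 absorbing, no mutation
and no new transposition — the null is drift-only by construction.
Control lineages use (Nₑ_C, t_C); selected lineages use
⌈Nₑ_S · b⌉ for t_S generations, where b ∈ (0, 1] is the fraction of flies
still able to breed at old age.  The default mode evolves one frequency
per family (the reference-average); a `per_site` mode evolves n
independent sites and averages them, as a sensitivity check (with one site
per family the two modes are distributionally identical; tests verify
this by a KS comparison).

Simulated data sets are classified exactly like observed ones: mean-based
(selected-replicate mean strictly above control mean; exact ties count
for neither side) and consistency-based (all-pairwise dominance, as in
approach #3).  The neutrality p-value is the raw fraction of simulations
whose statistic — by default S>C / (S>C + C>S), tied families excluded
from the denominator — is at least the observed one; an (r+1)/(n+1)
corrected variant exists behind a flag.  Simulations with an empty
denominator are excluded and counted; at biologically plausible Nₑ they
are rare.

Two opposing asymmetries matter scientifically and are both reproduced.
With left-skewed p₀ (most TEs rare), extra drift in the control lineages
(long lab histories) pushes low-frequency TEs to loss there, inflating the
*mean-based* S>C proportion — monotonically in control generations.  At
the same time a reduced old-age breeding fraction disperses the selected
replicates so strongly that all-replicate dominance over the tight control
cluster becomes rare in the S direction, leaving the *consistency-based*
counts control-dominated at every sweep point.  The acceptance suite
asserts both under a demography with Nₑ = 150, t_S = 58, b = 0.25, 2
control and 4 selected replicates, sweeping control generations from 29
to 464; this is a reproducible Monte-Carlo inequality under that
configuration, not a theorem.

RNG bookkeeping: one substream per simulation index, derived from the
master seed through `numpy.random.SeedSequence`, so enlarging `n_sims`
extends rather than reshuffles earlier runs.

## Statistical primitives

* Sequential-SS linear model: design columns are full indicator blocks
  per term (interactions by columnwise products); each term's SS is the
  drop in residual SS when its block is appended, its df the rank
  increment, both computed by least squares — nesting-induced aliasing
  then needs no special casing.  Sums of squares below
  1e-12 · (1 + ‖y‖²) are treated as zero; a constant response yields NA
  F-statistics with a warning rather than a 0/0.
* Welch t-test with Welch–Satterthwaite df; zero-variance corner cases
  return t = 0, p = 1 (equal means) or ±∞, p = 0 (unequal, flagged).
* Fisher's exact test is two-sided by the sum-of-probabilities-≤-observed
  convention (not doubling), with the conditional-MLE odds ratio.
* Pearson χ² without continuity correction.
* BH and Holm adjustments are NaN-aware (missing p-values propagate and do
  not count toward n).
* The exact multi-set intersection test exploits that, given its size, the
  intersection of uniform random sets is itself a uniform subset: the
  intersection-size pmf is built by chaining Hypergeometric(n, x, sᵢ)
  conditionals across sets, which reduces to the hypergeometric upper tail
  for two sets.  All sets are treated as random (none conditioned fixed).
  The suite verifies it against exhaustive enumeration over set
  placements for every size combination up to background 12 (pairs) and 7
  (triples), plus spot triples at 12.

## Synthetic data: what it does and does not emulate

The generator models the *output surfaces* of the upstream tools, not
reads: Gaussian noise (σ = 0.3 insertions, truncated at zero) around the
true per-population copy number at ~100 consensus positions per family,
and Beta-distributed latent site frequencies (concentration 5 around the
family mean — the dispersion is a free parameter, as no empirical value
exists for it) binomially resampled at 2 × pool size chromosomes.  Family
truths couple lognormal copy numbers (median 2, log-sd 1.1, chosen so
roughly the empirical share of a 179-family library survives the
retention filter) with Beta(0.6, 2.4) mean frequencies through a Gaussian
copula whose correlation is set to hit a target Spearman ρ (default −0.5);
one 179-family draw has a Spearman standard error near 0.08, so achieved
values scatter within roughly ±0.15 of the target.  Planted regime
effects (±δ copies in every selected population) are assigned to families
with baseline copies ≥ |δ| + 1 so that a negative effect cannot push a
family below the retention threshold, which would make the planted truth
unobservable by construction.  Sites are placed uniformly on five 20-Mb
chromosomes.

Deliberately not modelled: read-level noise (coverage is emulated after
normalization), linkage and physical clustering of insertions, piRNA
cluster structure, diet-specific effect reversals, and within-regime
heterogeneity of planted effects.  Passing tests therefore demonstrate
that the *statistical machinery* recovers known structure under its own
assumptions — not that those assumptions hold for any particular real
data set.

## Problem sizes

The test and acceptance runs use deliberately moderate sizes — 2,000
drift simulations for calibration checks, 300–500 per sweep point, 100
families, 100 null-study replicates, 10,000 Wright–Fisher trajectories for
the moment checks — enough for the Monte-Carlo bounds asserted (3–4
standard errors) while keeping a full run in a few minutes.  The
pipeline's defaults for real use are larger (5,000 simulations, the full
179-family library).

## Known limitations

* The ANOVA idiom inherits the source pipelines' pseudoreplication;
  p-values are comparable within this framework, not calibrated
  error rates for position-correlated coverage noise.
* The drift null treats a family's abundance as one frequency (or the
  mean of independent sites); transposition, selection and linkage are
  excluded by design, so the null is conservative about mechanisms that
  could mimic drift.
* The exact multi-set test assumes exchangeable families within the
  background; any structure (e.g. subclass-correlated callability) would
  distort its p-values.
* Diet-crossed designs are classified per diet by approach #3 but pooled
  across diets for approach #1's direction and effect size.
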