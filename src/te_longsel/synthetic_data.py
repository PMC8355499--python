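"""Seeded synthetic studies with the statistical structure the analyses assume.

The generator emulates the two pool-seq-derived surfaces the pipeline
consumes, not the sequencing reads behind them:

* per-position normalized TE coverage (insertions per haploid genome at
  each consensus position), modelled as Gaussian noise around the family's
  true per-population copy number, truncated at zero;
* genomic insertion sites with per-population frequencies, with latent site
  frequencies drawn from a Beta re-parameterized to the family's mean
  frequency and observed frequencies binomially resampled at pool size.

Family truths couple copy number and mean segregating frequency through a
Gaussian copula so that high-copy families tend to segregate at low
frequency (the classic abundance/frequency trade-off of active TE
families); the achieved Spearman correlation tracks a configurable target
(default -0.5, the middle of the empirically reported range).  Mean
frequencies are drawn left-skewed, Beta(0.6, 2.4), so most insertions are
rare.

Randomness is organised as one substream per (operation, family), derived
from the master seed with :class:`numpy.random.SeedSequence`, so adding
families or regenerating one table does not perturb the other draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import PopulationSample, StudyDesign
from .io_formats import (CoverageProfile, GeneInterval, InsertionSiteTable,
                         TEFamily)

# substream labels (kept stable across releases so seeds reproduce)
_STREAM_HIERARCHY = 0
_STREAM_FAMILIES = 1
_STREAM_COVERAGE = 2
_STREAM_INSERTIONS = 3
_STREAM_GENES = 4


def _rng(seed: int, stream: int, *keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream, *keys]))


@dataclass
class SynthConfig:
    """Parameters of one synthetic study.

    Defaults mirror the study conditions the pipeline is meant for: a
    179-family consensus library, coverage noise of 0.3 insertions per
    position, left-skewed Beta(0.6, 2.4) mean frequencies, a target
    copy-number/frequency Spearman correlation of -0.5, ~100 consensus
    positions per family and a 5 x 20 Mb synthetic genome.
    """

    n_families: int = 179
    sigma: float = 0.3
    freq_shape: tuple[float, float] = (0.6, 2.4)
    target_rho: float = -0.5
    coupling: float = 1.0
    n_positions: int = 100
    site_concentration: float = 5.0
    copies_log_mean: float = math.log(2.0)
    copies_log_sd: float = 1.1
    max_sites_per_family: int = 400
    n_s_gt_c: int = 0
    n_c_gt_s: int = 0
    delta: float = 1.0
    n_freq_shift_families: int = 0
    freq_shift: float = 0.0
    infinite_pool: bool = False
    chromosomes: Mapping[str, int] = field(
        default_factory=lambda: {f"chr{i}": 20_000_000 for i in range(1, 6)})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if min(self.freq_shape) <= 0:
            raise ValueError("Beta shapes must be > 0")
        if self.site_concentration <= 0:
            raise ValueError("site concentration must be > 0")
        if self.n_s_gt_c + self.n_c_gt_s > self.n_families:
            raise ValueError("planted families exceed n_families")


@dataclass(frozen=True)
class FamilyTruth:
    """Ground truth for one synthetic TE family.

    ``base_copies`` is the control-regime copy number per haploid genome;
    selected populations carry ``base_copies + delta``.  ``mean_freq`` is
    the family's mean segregating site frequency, ``n_sites`` the number of
    genomic insertion sites carrying it.
    """

    name: str
    base_copies: float
    mean_freq: float
    n_sites: int
    delta: float = 0.0
    freq_shift: float = 0.0

    def copies_for(self, sample: PopulationSample) -> float:
        c = self.base_copies + (self.delta if sample.regime == "S" else 0.0)
        return max(0.0, c)


_SUBCLASS_PROBS = {"LTR": 0.40, "non-LTR": 0.34, "TIR": 0.21, "other": 0.05}
_CLASS_OF = {"LTR": "RNA", "non-LTR": "RNA", "TIR": "DNA", "other": "RNA"}


def generate_hierarchy(config: SynthConfig) -> list[TEFamily]:
    """Synthetic consensus library with subclass labels and lengths."""
    rng = _rng(config.seed, _STREAM_HIERARCHY)
    names = [f"TEfam{i:03d}" for i in range(1, config.n_families + 1)]
    subclasses = rng.choice(list(_SUBCLASS_PROBS), size=config.n_families,
                            p=list(_SUBCLASS_PROBS.values()))
    lengths = rng.integers(800, 9000, size=config.n_families)
    return [
        TEFamily(name=n, subclass=str(sc), te_class=_CLASS_OF[str(sc)],
                 consensus_length=int(L))
        for n, sc, L in zip(names, subclasses, lengths)
    ]


def sample_reference_families(config: SynthConfig) -> list[FamilyTruth]:
    """Draw per-family truths with coupled copy number and mean frequency.

    A bivariate Gaussian copula with correlation ``2 sin(pi * rho_s / 6)``
    yields Spearman correlation ``rho_s = target_rho * coupling`` between
    the lognormal copy numbers and Beta mean frequencies.  Site counts are
    ``round(copies / mean_freq)`` (so copies ~ sum of site frequencies),
    capped at ``max_sites_per_family``.
    """
    rho_s = config.target_rho * config.coupling
    if not -1 < rho_s < 1:
        raise ValueError("target correlation must be in (-1, 1)")
    r = 2 * math.sin(math.pi * rho_s / 6)
    # one substream per family so enlarging the library never perturbs
    # the draws of existing families
    z = np.empty((config.n_families, 2))
    for i in range(config.n_families):
        rng = _rng(config.seed, _STREAM_FAMILIES, i)
        z1, z2 = rng.standard_normal(2)
        z[i] = (z1, r * z1 + math.sqrt(1 - r * r) * z2)
    u = sps.norm.cdf(z)
    a, b = config.freq_shape
    mean_freq = np.clip(sps.beta.ppf(u[:, 0], a, b), 1e-4, 1 - 1e-4)
    copies = np.exp(config.copies_log_mean
                    + config.copies_log_sd * sps.norm.ppf(u[:, 1]))
    n_sites = np.clip(np.round(copies / mean_freq), 1,
                      config.max_sites_per_family).astype(int)
    # plant effects on families with enough baseline copies that a negative
    # shift cannot push them below the downstream retention threshold
    min_base = abs(config.delta) + 1.0
    eligible = [i for i in range(config.n_families) if copies[i] >= min_base]
    n_planted = config.n_s_gt_c + config.n_c_gt_s
    if len(eligible) < n_planted:
        raise ValueError(
            f"only {len(eligible)} families have >= {min_base:.1f} copies; "
            f"cannot plant {n_planted} effects")
    delta_of = {}
    for i in eligible[:config.n_s_gt_c]:
        delta_of[i] = abs(config.delta)
    for i in eligible[config.n_s_gt_c:n_planted]:
        delta_of[i] = -abs(config.delta)
    truths = []
    for i in range(config.n_families):
        delta = delta_of.get(i, 0.0)
        shift = (config.freq_shift
                 if i < config.n_freq_shift_families else 0.0)
        truths.append(FamilyTruth(
            name=f"TEfam{i + 1:03d}",
            base_copies=float(copies[i]),
            mean_freq=float(mean_freq[i]),
            n_sites=int(n_sites[i]),
            delta=delta,
            freq_shift=shift,
        ))
    return truths


def _consensus_positions(length: int, n_positions: int) -> np.ndarray:
    """Up to ``n_positions`` distinct 1-based positions spanning a consensus."""
    pos = np.unique(np.linspace(1, length, num=min(n_positions, length),
                                dtype=int))
    return pos


def generate_coverage_data(truth: Sequence[FamilyTruth],
                           hierarchy: Sequence[TEFamily],
                           design: StudyDesign,
                           config: SynthConfig) -> CoverageProfile:
    """Per-position insertion estimates: ``max(0, N(copies, sigma))``."""
    lengths = {f.name: f.consensus_length for f in hierarchy}
    frames = []
    for i, fam in enumerate(truth):
        rng = _rng(config.seed, _STREAM_COVERAGE, i)
        pos = _consensus_positions(lengths[fam.name], config.n_positions)
        for s in design.samples:
            mu = fam.copies_for(s)
            vals = mu + config.sigma * rng.standard_normal(len(pos)) \
                if config.sigma > 0 else np.full(len(pos), mu)
            frames.append(pd.DataFrame({
                "family": fam.name, "sample": s.name, "pos": pos,
                "insertions": np.clip(vals, 0.0, None),
            }))
    data = pd.concat(frames, ignore_index=True)
    return CoverageProfile(data=data, hierarchy={f.name: f for f in hierarchy})


def generate_insertion_data(truth: Sequence[FamilyTruth],
                            design: StudyDesign,
                            config: SynthConfig) -> InsertionSiteTable:
    """Genomic insertion sites with binomially resampled pool frequencies.

    Latent site frequencies are Beta with mean ``mean_freq`` and
    concentration ``site_concentration``; a planted ``freq_shift`` raises
    the latent frequency in selected populations.  The observed frequency
    in a population is ``Binomial(2 * pool_size, q) / (2 * pool_size)``
    (or the latent ``q`` itself with ``infinite_pool``).
    """
    chrom_names = list(config.chromosomes)
    chrom_sizes = np.array([config.chromosomes[c] for c in chrom_names])
    rows = []
    c = config.site_concentration
    for i, fam in enumerate(truth):
        rng = _rng(config.seed, _STREAM_INSERTIONS, i)
        k = fam.n_sites
        ci = rng.integers(0, len(chrom_names), size=k)
        pos = rng.integers(1, chrom_sizes[ci] + 1)
        q = rng.beta(fam.mean_freq * c, (1 - fam.mean_freq) * c, size=k)
        rec = {
            "chrom": np.array(chrom_names)[ci], "pos": pos,
            "family": np.repeat(fam.name, k),
        }
        for s in design.samples:
            latent = q + (fam.freq_shift if s.regime == "S" else 0.0)
            latent = np.clip(latent, 0.0, 1.0)
            if config.infinite_pool:
                obs = latent
            else:
                n_chrom = 2 * s.pool_size
                obs = rng.binomial(n_chrom, latent) / n_chrom
            rec[f"freq_{s.name}"] = obs
        rows.append(pd.DataFrame(rec))
    data = pd.concat(rows, ignore_index=True)
    # uniform placement can collide; keep the first of any duplicated key
    data = data.drop_duplicates(subset=["chrom", "pos", "family"])
    return InsertionSiteTable(data=data.reset_index(drop=True),
                              sample_names=[s.name for s in design.samples])


def generate_gene_intervals(config: SynthConfig, n_genes: int = 200,
                            gene_length: tuple[int, int] = (1_000, 20_000),
                            ) -> list[GeneInterval]:
    """Uniformly placed non-validated gene models for annotation tests."""
    rng = _rng(config.seed, _STREAM_GENES)
    chrom_names = list(config.chromosomes)
    genes = []
    for i in range(n_genes):
        c = chrom_names[rng.integers(0, len(chrom_names))]
        size = int(rng.integers(*gene_length))
        start = int(rng.integers(1, config.chromosomes[c] - size))
        genes.append(GeneInterval(
            gene_id=f"gene{i + 1:04d}", chromosome=c, start=start,
            end=start + size - 1, strand="+" if rng.random() < 0.5 else "-",
        ))
    return genes


def generate_study(config: SynthConfig, design: StudyDesign):
    """Convenience bundle: (hierarchy, truths, coverage, insertions)."""
    hierarchy = generate_hierarchy(config)
    truths = sample_reference_families(config)
    profile = generate_coverage_data(truths, hierarchy, design, config)
    sites = generate_insertion_data(truths, design, config)
    return hierarchy, truths, profile, sites
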