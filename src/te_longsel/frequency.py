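"""Insertion-frequency analytics: family means, group contrasts, regime
differentiation and gene-proximity annotation.

The mean population frequency of a family's insertion sites is a proxy for
its evolutionary age and recent activity: young, active families segregate
at low frequency across many sites, old quiescent ones at high frequency.
Per-site and per-family regime tests run on arcsine-square-root
transformed frequencies, pooling site-by-population values as independent
observations (the same ANOVA idiom as the abundance models).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .abundance import LABEL_C, LABEL_NS, LABEL_S, AbundanceTable, \
    RegimeClassification
from .design import StudyDesign
from .io_formats import GeneInterval, InsertionSiteTable
from . import stats_core as st

logger = logging.getLogger(__name__)

RELATION_INSIDE = "inside"
RELATION_UPSTREAM = "upstream"
RELATION_DOWNSTREAM = "downstream"
RELATION_INTERGENIC = "intergenic"


@dataclass
class FamilyFrequencyTable:
    """Mean segregating frequency per (family, population).

    ``mean_freq`` averages the frequencies of a family's detected (non-NA)
    sites in each population; ``n_sites`` counts those sites.  A family
    with no detected site in a population is NaN there.
    """

    mean_freq: pd.DataFrame
    n_sites: pd.DataFrame

    def population_means(self) -> pd.Series:
        """Family mean frequency averaged across populations."""
        return self.mean_freq.mean(axis=1)


@dataclass(frozen=True)
class SiteTestResult:
    """Regime differentiation of one genomic insertion site."""

    chrom: str
    pos: int
    family: str
    p: float
    significant: bool
    direction: str | None  # "S" or "C" when significant, else None
    gene_id: str | None = None
    relation: str | None = None


def family_mean_frequency(sites: InsertionSiteTable) -> FamilyFrequencyTable:
    """Average per-population frequencies over each family's detected sites."""
    if len(sites.data) == 0:
        raise ValueError("insertion table is empty")
    freqs = sites.frequencies()
    freqs["family"] = sites.data["family"].to_numpy()
    grouped = freqs.groupby("family")
    return FamilyFrequencyTable(
        mean_freq=grouped.mean(),
        n_sites=grouped.count(),
    )


def frequency_group_comparison(freqs: Mapping[str, float],
                               classifications: Sequence[RegimeClassification],
                               top_n: int | None = None) -> st.TestResult | None:
    """Welch t-test of reference frequencies between C>S and S>C families.

    ``freqs`` maps family name to a reference mean frequency (for instance
    from a deeply sequenced natural population).  With ``top_n`` each group
    is restricted to its ``top_n`` members by |log2fc| (ties broken by
    family name so the choice is deterministic).  Returns None when either
    group has fewer than 2 members with a reference frequency.
    """
    def group(label: str) -> list[float]:
        members = [c for c in classifications
                   if c.label == label and c.family in freqs]
        if top_n is not None:
            members.sort(key=lambda c: (-abs(c.log2fc), c.family))
            members = members[:top_n]
        return [freqs[c.family] for c in members]

    g_c, g_s = group(LABEL_C), group(LABEL_S)
    if min(len(g_c), len(g_s)) < 2:
        logger.warning("frequency_group_comparison: group too small")
        return None
    return st.welch_t_test(g_s, g_c)


def abundance_frequency_correlation(table: AbundanceTable,
                                    freqs: FamilyFrequencyTable | Mapping[str, float],
                                    per_population: bool = False):
    """Spearman correlation of family copy number with mean frequency.

    With ``per_population`` one correlation per shared population is
    returned (dict); otherwise a single correlation on family means across
    populations.
    """
    if isinstance(freqs, FamilyFrequencyTable):
        freq_mean = freqs.mean_freq
    else:
        freq_mean = pd.DataFrame({"ref": pd.Series(freqs)})
    shared = table.data.index.intersection(freq_mean.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared families")
    if per_population:
        out = {}
        for col in freq_mean.columns:
            if col not in table.data.columns:
                continue
            mask = freq_mean.loc[shared, col].notna()
            out[col] = st.rank_correlation(
                table.data.loc[shared[mask], col],
                freq_mean.loc[shared[mask], col])
        return out
    a = table.data.loc[shared].mean(axis=1)
    f = freq_mean.loc[shared].mean(axis=1)
    mask = f.notna()
    return st.rank_correlation(a[mask], f[mask])


def _site_terms(design: StudyDesign) -> list[str]:
    return ["Diet", "Regime", "Diet:Regime"] if design.has_diets else ["Regime"]


def site_differentiation_test(sites: InsertionSiteTable, design: StudyDesign,
                              alpha: float = 0.05) -> list[SiteTestResult]:
    """Per-site regime ANOVA on transformed frequencies with Bonferroni
    control at ``alpha`` over the number of sites actually tested.

    Sites are tested on the populations where they were observed (non-NA);
    a site with fewer than two populations per regime is skipped and
    logged.  Direction is reported only for significant sites.
    """
    regime_of = design.regime_of()
    diet_of = {s.name: s.diet for s in design.samples}
    terms = _site_terms(design)
    freqs = sites.frequencies()
    tested: list[tuple[str, int, str, float, float]] = []
    skipped = 0
    for i in range(len(sites.data)):
        row = freqs.iloc[i]
        obs = row.dropna()
        regimes = np.array([regime_of[s] for s in obs.index])
        if min((regimes == "C").sum(), (regimes == "S").sum()) < 2:
            skipped += 1
            continue
        factors = pd.DataFrame({
            "Regime": regimes,
            "Diet": [diet_of[s] for s in obs.index],
        })
        y = st.arcsine_sqrt(obs.to_numpy(dtype=float))
        try:
            with warnings.catch_warnings():
                # fixed sites (all frequencies identical) are routine
                warnings.simplefilter("ignore", UserWarning)
                lm = st.fit_fixed_lm(y, factors, terms)
            p = lm.term("Regime").p
        except ValueError:
            skipped += 1
            continue
        delta = y[regimes == "S"].mean() - y[regimes == "C"].mean()
        key = sites.data.iloc[i]
        tested.append((key["chrom"], int(key["pos"]), key["family"],
                       float(p), float(delta)))
    if skipped:
        logger.info("site_differentiation_test: skipped %d sites", skipped)
    if not tested:
        return []
    threshold = st.bonferroni_threshold(alpha, len(tested))
    out = []
    for chrom, pos, fam, p, delta in tested:
        sig = not math.isnan(p) and p < threshold
        direction = None
        if sig:
            direction = "S" if delta > 0 else "C"
        out.append(SiteTestResult(chrom=chrom, pos=pos, family=fam, p=p,
                                  significant=sig, direction=direction))
    return out


def family_frequency_regime_test(sites: InsertionSiteTable,
                                 design: StudyDesign,
                                 fdr: float = 0.05) -> pd.DataFrame:
    """Per-family regime test on pooled site-by-population frequencies.

    For each family with at least two sites, all transformed site
    frequencies are modelled with Regime + Population (or Diet + Regime +
    Diet:Regime for diet-crossed designs); regime-term p-values are
    BH-adjusted across families.  Returns a frame indexed by family with
    ``p``, ``p_adjusted``, ``significant`` and the regime difference of
    transformed means.
    """
    regime_of = design.regime_of()
    diet_of = {s.name: s.diet for s in design.samples}
    terms = (["Diet", "Regime", "Diet:Regime"] if design.has_diets
             else ["Regime", "Population"])
    freqs = sites.frequencies()
    freqs["family"] = sites.data["family"].to_numpy()
    rows = []
    for fam, sub in freqs.groupby("family"):
        long = sub.drop(columns="family").melt(
            var_name="sample", value_name="freq").dropna()
        n_sites = len(sub)
        if n_sites < 2 or len(long) < 4:
            rows.append((fam, n_sites, math.nan, math.nan))
            continue
        factors = pd.DataFrame({
            "Regime": long["sample"].map(regime_of),
            "Population": long["sample"],
            "Diet": long["sample"].map(diet_of),
        })
        y = st.arcsine_sqrt(long["freq"].to_numpy(dtype=float))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                lm = st.fit_fixed_lm(y, factors, terms)
            p = lm.term("Regime").p
        except ValueError:
            p = math.nan
        s_mask = factors["Regime"].to_numpy() == "S"
        delta = float(y[s_mask].mean() - y[~s_mask].mean())
        rows.append((fam, n_sites, p, delta))
    df = pd.DataFrame(rows, columns=["family", "n_sites", "p", "delta"])
    df["p_adjusted"] = st.bh_adjust(df["p"].to_numpy())
    df["significant"] = df["p_adjusted"] < fdr
    return df.set_index("family")


def jointly_significant(family_tests: pd.DataFrame,
                        classifications: Sequence[RegimeClassification]
                        ) -> list[str]:
    """Families significant for both abundance and frequency."""
    abundance_sig = {c.family for c in classifications if c.label != LABEL_NS}
    freq_sig = set(family_tests.index[family_tests["significant"]])
    return sorted(abundance_sig & freq_sig)


def annotate_sites(sites: InsertionSiteTable, genes: Sequence[GeneInterval],
                   window: int = 1000) -> pd.DataFrame:
    """Relate each insertion site to the nearest gene within ``window`` bp.

    Relations: ``inside`` (gene start <= pos <= end), ``upstream`` /
    ``downstream`` (within ``window`` of the gene edge, inclusive; side
    resolved by gene strand) or ``intergenic``.  When several genes
    qualify, the nearest is reported; exact ties go to the
    lexicographically smallest gene id.
    """
    by_chrom: dict[str, list[GeneInterval]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    out = sites.data[["chrom", "pos", "family"]].copy()
    gene_ids, relations, distances = [], [], []
    for chrom, pos in zip(out["chrom"], out["pos"]):
        candidates: list[tuple[int, str, str]] = []  # (distance, id, relation)
        for g in by_chrom.get(chrom, ()):
            if g.start <= pos <= g.end:
                candidates.append((0, g.gene_id, RELATION_INSIDE))
                continue
            if pos < g.start:
                d = g.start - pos
                side = RELATION_UPSTREAM if g.strand == "+" \
                    else RELATION_DOWNSTREAM
            else:
                d = pos - g.end
                side = RELATION_DOWNSTREAM if g.strand == "+" \
                    else RELATION_UPSTREAM
            if d <= window:
                candidates.append((d, g.gene_id, side))
        if candidates:
            d, gid, rel = min(candidates)
            gene_ids.append(gid)
            relations.append(rel)
            distances.append(d)
        else:
            gene_ids.append(None)
            relations.append(RELATION_INTERGENIC)
            distances.append(np.nan)
    out["gene_id"] = gene_ids
    out["relation"] = relations
    out["distance"] = distances
    return out
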