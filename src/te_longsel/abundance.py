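"""Family-level genomic TE abundance: filtering, classification, content.

Copy numbers come from per-position normalized coverage: averaging a
family's values across consensus positions gives its mean number of
insertions per haploid genome in a population.  Families are screened for
regime differences with three complementary approaches of increasing
stringency:

#1  per-study ANOVA on per-position values (Regime + Population-within-
    Regime, or Regime + Diet + Regime:Diet for diet-crossed designs), with
    a family called only when the regime term survives Bonferroni
    correction at alpha across retained families AND the regime means
    differ by more than ``delta_min`` insertions;
#2  a cross-study model on arcsine-square-root transformed proportions of
    each family relative to the population's total TE content (Study +
    Regime + Study:Regime), significant at an FDR threshold;
#3  a consistency call with no test at all: every selected population must
    exceed every control population (or vice versa).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import NO_DIET, StudyDesign
from .io_formats import CoverageProfile, TEFamily
from . import stats_core as st

logger = logging.getLogger(__name__)

LABEL_S = "S>C"
LABEL_C = "C>S"
LABEL_NS = "NS"


@dataclass
class AbundanceTable:
    """Mean insertions per haploid genome, families x populations."""

    data: pd.DataFrame  # index: family, columns: sample names

    def __post_init__(self) -> None:
        if (self.data.to_numpy() < 0).any():
            raise ValueError("abundance values must be >= 0")

    @property
    def families(self) -> list[str]:
        return list(self.data.index)

    def regime_means(self, design: StudyDesign) -> pd.DataFrame:
        """Per-family mean abundance per regime (pooled across diets)."""
        out = {}
        for regime in ("C", "S"):
            cols = [s.name for s in design.samples_for(regime=regime)]
            out[regime] = self.data[cols].mean(axis=1)
        return pd.DataFrame(out)


@dataclass(frozen=True)
class RegimeClassification:
    """Regime label for one family with its supporting statistics."""

    family: str
    label: str
    p_raw: float
    p_adjusted: float
    log2fc: float
    delta_insertion: float

    def __post_init__(self) -> None:
        if self.label not in (LABEL_S, LABEL_C, LABEL_NS):
            raise ValueError(f"unknown label {self.label!r}")


def filter_families(profile: CoverageProfile,
                    samples: Sequence[str] | None = None) -> list[str]:
    """Families whose study-average coverage clears the retention rule.

    A family is retained iff, averaging values across all populations of
    the study at each consensus position, at least 80% of positions have an
    average of at least 0.5 insertions (both bounds inclusive).  Families
    with zero positions are excluded with a warning.
    """
    df = profile.data
    if samples is not None:
        df = df[df["sample"].isin(samples)]
    retained = []
    for fam, sub in df.groupby("family", observed=True):
        pos_means = sub.groupby("pos")["insertions"].mean()
        if len(pos_means) == 0:
            warnings.warn(f"family {fam} has zero positions; excluded",
                          stacklevel=2)
            continue
        if (pos_means >= 0.5).mean() >= 0.8:
            retained.append(fam)
    return sorted(retained)


def estimate_abundance(profile: CoverageProfile,
                       retained: Sequence[str]) -> AbundanceTable:
    """Average per-position values into one copy-number estimate per
    (family, population)."""
    if not retained:
        raise ValueError("retained family list is empty")
    df = profile.data[profile.data["family"].isin(retained)]
    wide = (df.groupby(["family", "sample"])["insertions"].mean()
              .unstack("sample"))
    return AbundanceTable(data=wide.loc[sorted(retained)])


def fold_changes(table: AbundanceTable, design: StudyDesign) -> pd.DataFrame:
    """Per-family log2(S/C) fold change and S-minus-C difference.

    No pseudo-count is used: the retention filter makes zero regime means
    practically impossible, and a nonpositive mean surfaces as NaN rather
    than silently shifting values.
    """
    means = table.regime_means(design)
    delta = means["S"] - means["C"]
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(means["S"] / means["C"])
    bad = (means["S"] <= 0) | (means["C"] <= 0)
    if bad.any():
        warnings.warn(
            f"nonpositive regime mean for {list(means.index[bad])}: "
            "log2fc set to NaN", stacklevel=2)
        log2fc[bad] = np.nan
    return pd.DataFrame({"log2fc": log2fc, "delta_insertion": delta})


def _approach1_terms(design: StudyDesign) -> list[str]:
    if design.has_diets:
        return ["Regime", "Diet", "Regime:Diet"]
    return ["Regime", "Population"]


def classify_approach1(profile: CoverageProfile, design: StudyDesign,
                       alpha: float = 0.01,
                       delta_min: float = 0.3) -> list[RegimeClassification]:
    """Per-study ANOVA on per-position coverage values (approach #1).

    The regime-term p-value is Bonferroni-corrected across retained
    families; a family is labelled by the sign of its regime difference
    only when the corrected test is significant AND |delta| > delta_min.
    """
    retained = filter_families(profile)
    if not retained:
        return []
    table = estimate_abundance(profile, retained)
    fc = fold_changes(table, design)
    n = len(retained)
    threshold = st.bonferroni_threshold(alpha, n)
    regime_of = design.regime_of()
    diet_of = {s.name: s.diet for s in design.samples}
    terms = _approach1_terms(design)
    out = []
    for fam in retained:
        sub = profile.for_family(fam)
        factors = pd.DataFrame({
            "Regime": sub["sample"].map(regime_of),
            "Population": sub["sample"],
            "Diet": sub["sample"].map(diet_of),
        })
        try:
            lm = st.fit_fixed_lm(sub["insertions"].to_numpy(), factors, terms)
            p = lm.term("Regime").p
        except ValueError as exc:
            logger.warning("approach1: family %s unfittable (%s)", fam, exc)
            p = math.nan
        delta = float(fc.loc[fam, "delta_insertion"])
        log2 = float(fc.loc[fam, "log2fc"])
        significant = (not math.isnan(p)) and p < threshold \
            and abs(delta) > delta_min
        label = LABEL_NS
        if significant:
            label = LABEL_S if delta > 0 else LABEL_C
        out.append(RegimeClassification(
            family=fam, label=label, p_raw=p,
            p_adjusted=min(1.0, p * n) if not math.isnan(p) else math.nan,
            log2fc=log2, delta_insertion=delta,
        ))
    return out


def classify_approach2(tables: Mapping[str, AbundanceTable],
                       designs: Mapping[str, StudyDesign],
                       fdr: float = 0.05) -> list[RegimeClassification]:
    """Cross-study model on transformed TE-content proportions (approach #2).

    Operates on the families retained in *every* study.  The response is
    asin(sqrt(family copies / total TE copies in that population)); one
    model per family with terms Study, Regime, Study:Regime; regime-term
    p-values are BH-adjusted across families.
    """
    studies = sorted(tables)
    if len(studies) < 2:
        raise ValueError("approach #2 needs at least two studies")
    common = sorted(set.intersection(
        *(set(tables[s].families) for s in studies)))
    if not common:
        return []
    long = []
    for study in studies:
        data = tables[study].data
        totals = data.sum(axis=0)  # total TE content per population
        regime_of = designs[study].regime_of()
        for sample in data.columns:
            props = st.arcsine_sqrt(
                (data[sample] / totals[sample]).clip(0, 1).to_numpy())
            long.append(pd.DataFrame({
                "family": data.index, "Study": study,
                "Regime": regime_of[sample], "sample": sample, "y": props,
            }))
    long_df = pd.concat(long, ignore_index=True)
    pvals, deltas = [], []
    for fam in common:
        sub = long_df[long_df["family"] == fam]
        lm = st.fit_fixed_lm(sub["y"].to_numpy(),
                             sub[["Study", "Regime"]],
                             ["Study", "Regime", "Study:Regime"])
        pvals.append(lm.term("Regime").p)
        deltas.append(sub.loc[sub["Regime"] == "S", "y"].mean()
                      - sub.loc[sub["Regime"] == "C", "y"].mean())
    adjusted = st.bh_adjust(pvals)
    out = []
    for fam, p, padj, d in zip(common, pvals, adjusted, deltas):
        label = LABEL_NS
        if not math.isnan(padj) and padj < fdr:
            label = LABEL_S if d > 0 else LABEL_C
        out.append(RegimeClassification(
            family=fam, label=label, p_raw=float(p), p_adjusted=float(padj),
            log2fc=math.nan, delta_insertion=float(d),
        ))
    return out


def classify_approach3(table: AbundanceTable, design: StudyDesign,
                       diet: str | None = None) -> list[RegimeClassification]:
    """Consistency call (approach #3): all-pairwise regime dominance.

    A family is S>C iff the smallest selected population value exceeds the
    largest control value (strictly), C>S in the mirror case, NS otherwise.
    For diet-crossed designs pass ``diet`` to classify within one diet;
    see :func:`classify_approach3_by_diet`.
    """
    s_cols = [s.name for s in design.samples_for(regime="S", diet=diet)]
    c_cols = [s.name for s in design.samples_for(regime="C", diet=diet)]
    if not s_cols or not c_cols:
        raise ValueError("need at least one population per regime")
    out = []
    for fam in table.families:
        s_vals = table.data.loc[fam, s_cols].to_numpy(dtype=float)
        c_vals = table.data.loc[fam, c_cols].to_numpy(dtype=float)
        if s_vals.min() > c_vals.max():
            label = LABEL_S
        elif s_vals.max() < c_vals.min():
            label = LABEL_C
        else:
            label = LABEL_NS
        out.append(RegimeClassification(
            family=fam, label=label, p_raw=math.nan, p_adjusted=math.nan,
            log2fc=math.nan,
            delta_insertion=float(s_vals.mean() - c_vals.mean()),
        ))
    return out


def classify_approach3_by_diet(table: AbundanceTable, design: StudyDesign,
                               ) -> dict[str, list[RegimeClassification]]:
    """Approach #3 within each diet of a diet-crossed design."""
    if not design.has_diets:
        return {NO_DIET: classify_approach3(table, design)}
    return {d: classify_approach3(table, design, diet=d)
            for d in design.diets}


def label_counts(classifications: Sequence[RegimeClassification]
                 ) -> dict[str, int]:
    counts = {LABEL_S: 0, LABEL_C: 0, LABEL_NS: 0}
    for c in classifications:
        counts[c.label] += 1
    return counts


def magnitude_comparisons(classifications: Mapping[str, Sequence[RegimeClassification]]
                          ) -> dict:
    """Magnitude-of-change contrasts between TE groups and studies.

    Per study: Welch t-tests of |log2fc| and of |delta| between the C>S and
    S>C groups.  Across studies: one-way ANOVA of |log2fc| with Study as
    the single term, followed by pairwise Welch comparisons with Holm
    adjustment.
    """
    per_study_fc: dict[str, st.TestResult | None] = {}
    per_study_delta: dict[str, st.TestResult | None] = {}
    anova_vals, anova_studies = [], []
    for study, cls in classifications.items():
        fc_s = [abs(c.log2fc) for c in cls if c.label == LABEL_S
                and not math.isnan(c.log2fc)]
        fc_c = [abs(c.log2fc) for c in cls if c.label == LABEL_C
                and not math.isnan(c.log2fc)]
        d_s = [abs(c.delta_insertion) for c in cls if c.label == LABEL_S]
        d_c = [abs(c.delta_insertion) for c in cls if c.label == LABEL_C]
        per_study_fc[study] = (st.welch_t_test(fc_c, fc_s)
                               if min(len(fc_c), len(fc_s)) >= 2 else None)
        per_study_delta[study] = (st.welch_t_test(d_c, d_s)
                                  if min(len(d_c), len(d_s)) >= 2 else None)
        for c in cls:
            if not math.isnan(c.log2fc):
                anova_vals.append(abs(c.log2fc))
                anova_studies.append(study)
    design = pd.DataFrame({"Study": anova_studies})
    multi_study = len(set(anova_studies)) >= 2
    anova = (st.fit_fixed_lm(anova_vals, design, ["Study"])
             if multi_study else None)
    pairwise = (st.pairwise_group_comparison(anova_vals, anova_studies)
                if multi_study else [])
    return {
        "fc_magnitude_by_study": per_study_fc,
        "delta_magnitude_by_study": per_study_delta,
        "anova_study": anova,
        "pairwise_study": pairwise,
    }


def content_tests(tables: Mapping[str, AbundanceTable],
                  hierarchy: Sequence[TEFamily],
                  designs: Mapping[str, StudyDesign]) -> dict:
    """Total and subclass-specific genomic TE content models.

    Per-population totals (summed copy numbers, overall and within each
    subclass) are modelled with Study + Regime + Study:Regime; within-study
    regime contrasts use pairwise Welch comparisons on the totals.
    """
    subclass_of = {f.name: f.subclass for f in hierarchy}
    scopes = {"total": None, "LTR": "LTR", "non-LTR": "non-LTR", "TIR": "TIR"}
    results = {}
    for scope_name, subclass in scopes.items():
        rows = []
        for study, table in tables.items():
            data = table.data
            if subclass is not None:
                fams = [f for f in data.index
                        if subclass_of.get(f) == subclass]
                if not fams:
                    logger.info("content_tests: no %s families in %s; skipped",
                                subclass, study)
                    continue
                data = data.loc[fams]
            regime_of = designs[study].regime_of()
            for sample in data.columns:
                rows.append({"Study": study, "Regime": regime_of[sample],
                             "total": float(data[sample].sum())})
        if not rows:
            continue
        df = pd.DataFrame(rows)
        model = st.fit_fixed_lm(df["total"].to_numpy(),
                                df[["Study", "Regime"]],
                                ["Study", "Regime", "Study:Regime"])
        within = {}
        for study, sub in df.groupby("Study"):
            c = sub.loc[sub["Regime"] == "C", "total"].to_numpy()
            s = sub.loc[sub["Regime"] == "S", "total"].to_numpy()
            within[study] = (st.welch_t_test(s, c)
                             if min(len(c), len(s)) >= 2 else None)
        results[scope_name] = {"model": model, "within_study": within}
    return results


def subclass_enrichment(classifications: Sequence[RegimeClassification],
                        hierarchy: Sequence[TEFamily]) -> dict:
    """Fisher tests for TE-type enrichment within the S>C and C>S groups.

    For each group and each type (TIR subclass; DNA class) the 2x2 table
    crosses group membership with type membership over the background of
    all classified (retained) families.
    """
    subclass_of = {f.name: f.subclass for f in hierarchy}
    class_of = {f.name: f.te_class for f in hierarchy}
    background = [c.family for c in classifications]
    results = {}
    for group in (LABEL_S, LABEL_C):
        members = {c.family for c in classifications if c.label == group}
        if not members:
            logger.info("subclass_enrichment: empty group %s skipped", group)
            continue
        for type_name, pred in (
                ("TIR", lambda f: subclass_of.get(f) == "TIR"),
                ("DNA", lambda f: class_of.get(f) == "DNA")):
            in_g_t = sum(1 for f in members if pred(f))
            in_g_n = len(members) - in_g_t
            out_t = sum(1 for f in background
                        if f not in members and pred(f))
            out_n = len(background) - len(members) - out_t
            results[(group, type_name)] = st.fisher_exact_2x2(
                [[in_g_t, in_g_n], [out_t, out_n]])
    return results


def correct_counts_by_copies(counts: pd.DataFrame,
                             table: AbundanceTable) -> pd.DataFrame:
    """Divide expression read counts by genomic copy number.

    Families absent from the abundance table (those that failed the
    retention filter) are assumed to have a single genomic copy; a zero
    copy number is treated as one with a warning.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be >= 0")
    divisors = pd.DataFrame(1.0, index=counts.index, columns=counts.columns)
    shared_f = counts.index.intersection(table.data.index)
    shared_s = counts.columns.intersection(table.data.columns)
    divisors.loc[shared_f, shared_s] = table.data.loc[shared_f, shared_s]
    zero = divisors == 0
    if zero.to_numpy().any():
        warnings.warn("zero copy number treated as 1", stacklevel=2)
        divisors = divisors.mask(zero, 1.0)
    return counts / divisors
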