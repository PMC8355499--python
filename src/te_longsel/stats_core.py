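"""Statistical primitives shared by all analysis stages.

The fixed-effect linear model uses *sequential* (type-I) sums of squares
with every term tested against the residual mean square, matching the
default behaviour of ``aov`` in R; nesting (e.g. replicate populations
within regime) is expressed by giving each population a globally unique
label, so the rank increment of the population term automatically excludes
the regime contrast it aliases.

Pairwise group comparisons use Welch t-tests with Holm adjustment in place
of a studentized-range (Tukey HSD) post hoc; conclusions drawn from them
are qualitative orderings of group means, for which the two procedures
agree in practice.

The exact multi-set intersection test treats each of the ``m`` sets as an
independent uniform draw of fixed size from a common background.  The
intersection-size distribution is built by chaining hypergeometric
conditionals: the intersection of the first ``j`` sets, given its size
``x``, is itself a uniform ``x``-subset, so intersecting with the next
(independent) set of size ``s`` adds a Hypergeometric(n, x, s) step.  For
two sets this reduces to the classical hypergeometric upper tail.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult", "TermStat", "LinearModelResult", "PairwiseComparison",
    "fit_fixed_lm", "welch_t_test", "rank_correlation",
    "bonferroni_threshold", "bh_adjust", "fisher_exact_2x2",
    "chi_square_contingency", "multiset_intersection_test", "arcsine_sqrt",
    "pairwise_group_comparison",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a scalar hypothesis test."""

    statistic: float
    p: float
    df: float | tuple[float, float] | None = None
    estimate: float | None = None
    method: str = ""

    def __post_init__(self) -> None:
        if not math.isnan(self.p) and not 0 <= self.p <= 1:
            raise ValueError(f"p-value {self.p} outside [0, 1]")


@dataclass(frozen=True)
class TermStat:
    """Sequential ANOVA line for one model term."""

    name: str
    df: int
    ss: float
    f: float
    p: float


@dataclass
class LinearModelResult:
    """Sequential (type-I) ANOVA decomposition of a fixed-effect model."""

    terms: list[TermStat]
    residual_df: int
    residual_ss: float
    coefficients: np.ndarray
    total_ss: float

    def term(self, name: str) -> TermStat:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(f"no term {name!r} in model")


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    statistic: float
    p_raw: float
    p_adjusted: float
    estimate: float


def _dummies(values: np.ndarray) -> np.ndarray:
    """Full (non-contrast) indicator matrix with deterministic level order."""
    levels = sorted(set(values))
    return np.column_stack([(values == lev).astype(float) for lev in levels])


def _term_columns(design: pd.DataFrame, term: str) -> np.ndarray:
    parts = term.split(":")
    mats = [_dummies(design[p].astype(str).to_numpy()) for p in parts]
    out = mats[0]
    for m in mats[1:]:
        out = (out[:, :, None] * m[:, None, :]).reshape(len(design), -1)
    return out


def _rss(x: np.ndarray, y: np.ndarray) -> tuple[float, int, np.ndarray]:
    """Residual sum of squares, rank and minimum-norm coefficients."""
    coef, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    return float(resid @ resid), int(rank), coef


def fit_fixed_lm(response: Sequence[float], design: pd.DataFrame,
                 terms: Sequence[str]) -> LinearModelResult:
    """Fit a fixed-effect linear model and decompose it sequentially.

    Parameters
    ----------
    response
        Numeric response vector.
    design
        One categorical column per factor named in ``terms``.
    terms
        Ordered term list; interactions are written ``A:B``.  Sums of
        squares are sequential in this order and every F uses the residual
        mean square.

    Raises
    ------
    ValueError
        If a term adds no estimable contrast at all (rank deficiency beyond
        nesting-induced aliasing) or the model leaves no observation for the
        residual.
    """
    y = np.asarray(response, dtype=float)
    n = len(y)
    if len(design) != n:
        raise ValueError("response and design lengths differ")
    x = np.ones((n, 1))
    rss_prev, rank_prev, _ = _rss(x, y)
    total_ss = rss_prev  # SS about the mean
    if n < len(terms) + 1:
        raise ValueError("fewer observations than model terms")
    seq: list[tuple[str, int, float]] = []
    coef = np.zeros(1)
    for term in terms:
        x = np.hstack([x, _term_columns(design, term)])
        rss_new, rank_new, coef = _rss(x, y)
        df_term = rank_new - rank_prev
        ss_term = max(0.0, rss_prev - rss_new)
        if df_term == 0 and len(set(map(tuple, design[term.split(":")].astype(str).itertuples(index=False)))) > 1:
            raise ValueError(
                f"term {term!r} is completely aliased by preceding terms"
            )
        seq.append((term, df_term, ss_term))
        rss_prev, rank_prev = rss_new, rank_new
    residual_df = n - rank_prev
    residual_ss = rss_prev
    if residual_df == 0:
        warnings.warn("zero residual df: F statistics undefined", stacklevel=2)
    # numerically-zero sums of squares (e.g. a constant response) are
    # detected at the scale of the data, not by exact equality
    tiny = 1e-12 * (1.0 + float(y @ y))
    ms_res = residual_ss / residual_df if residual_df > 0 else math.nan
    stats = []
    for name, df_t, ss_t in seq:
        if df_t == 0:
            stats.append(TermStat(name, 0, ss_t, math.nan, math.nan))
            continue
        if residual_df == 0 or residual_ss < tiny or math.isnan(ms_res):
            if ss_t < tiny or residual_df == 0:
                f = p = math.nan
                if residual_df > 0 and residual_ss < tiny and ss_t < tiny:
                    warnings.warn(
                        f"term {name!r}: degenerate (constant) response",
                        stacklevel=2)
            else:
                f, p = math.inf, 0.0
            stats.append(TermStat(name, df_t, ss_t, f, p))
            continue
        f = (ss_t / df_t) / ms_res
        p = float(sps.f.sf(f, df_t, residual_df))
        stats.append(TermStat(name, df_t, ss_t, f, p))
    return LinearModelResult(
        terms=stats, residual_df=residual_df, residual_ss=residual_ss,
        coefficients=coef, total_ss=total_ss,
    )


def welch_t_test(x: Sequence[float], y: Sequence[float],
                 two_sided: bool = True) -> TestResult:
    """Welch unequal-variance t-test with Welch–Satterthwaite df."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    nx, ny = len(x), len(y)
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    diff = mx - my
    if se2 == 0:
        if diff == 0:
            return TestResult(0.0, 1.0, df=float(nx + ny - 2), estimate=0.0,
                              method="welch_t")
        warnings.warn("zero variance in both samples with unequal means",
                      stacklevel=2)
        return TestResult(math.copysign(math.inf, diff), 0.0,
                          df=float(nx + ny - 2), estimate=diff,
                          method="welch_t")
    t = diff / math.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = float(sps.t.sf(abs(t), df))
    p = min(1.0, 2 * p) if two_sided else (p if t > 0 else 1 - p)
    return TestResult(float(t), p, df=float(df), estimate=float(diff),
                      method="welch_t")


def rank_correlation(x: Sequence[float], y: Sequence[float],
                     method: str = "spearman") -> TestResult:
    """Spearman's rho (t approximation) or Pearson's r with p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("x and y must be paired")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero variance: correlation undefined", stacklevel=2)
        return TestResult(math.nan, math.nan, estimate=math.nan,
                          method=method)
    if method == "spearman":
        rho, p = sps.spearmanr(x, y)
    elif method == "pearson":
        rho, p = sps.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(float(rho), float(p), df=float(len(x) - 2),
                      estimate=float(rho), method=method)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance cut-off ``alpha / n_tests``."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (NaN-aware)."""
    p = np.asarray(p, float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def fisher_exact_2x2(table, two_sided: bool = True) -> TestResult:
    """Fisher's exact test on a 2x2 count table.

    The two-sided p-value sums hypergeometric outcomes with probability no
    larger than the observed one (R's convention, not doubling); the
    estimate is the conditional maximum-likelihood odds ratio.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with nonnegative integers")
    if 0 in t.sum(axis=0) or 0 in t.sum(axis=1):
        warnings.warn("zero margin: p = 1, odds ratio undefined", stacklevel=2)
        return TestResult(math.nan, 1.0, estimate=math.nan,
                          method="fisher_exact")
    alternative = "two-sided" if two_sided else "greater"
    _, p = sps.fisher_exact(t, alternative=alternative)
    odds = sps.contingency.odds_ratio(t, kind="conditional").statistic
    return TestResult(float(odds), float(min(p, 1.0)), estimate=float(odds),
                      method="fisher_exact")


def chi_square_contingency(table) -> TestResult:
    """Pearson chi-square test of independence (no continuity correction)."""
    t = np.asarray(table, dtype=float)
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")
    chi2, p, dof, _ = sps.chi2_contingency(t, correction=False)
    return TestResult(float(chi2), float(p), df=float(dof),
                      method="chi_square")


def multiset_intersection_test(background_n: int, set_sizes: Sequence[int],
                               observed_k: int) -> TestResult:
    """Exact upper-tail test for the intersection of m random sets.

    Computes ``P(|S_1 ∩ ... ∩ S_m| >= observed_k)`` when each set ``S_i`` of
    fixed size is drawn uniformly and independently from a background of
    ``background_n`` elements.  The estimate is the expected intersection
    size ``n * prod(s_i / n)``.
    """
    sizes = list(set_sizes)
    if len(sizes) < 2:
        raise ValueError("need at least two sets")
    if any(s < 0 or s > background_n for s in sizes):
        raise ValueError("set sizes must be within [0, background_n]")
    if observed_k < 0 or observed_k > min(sizes):
        raise ValueError("observed_k must be within [0, min(set_sizes)]")
    n = background_n
    expected = n * float(np.prod([s / n for s in sizes]))
    if observed_k == 0:  # the whole distribution: certain
        return TestResult(0.0, 1.0, estimate=expected,
                          method="multiset_intersection")
    pmf = np.zeros(n + 1)
    pmf[sizes[0]] = 1.0
    for s in sizes[1:]:
        new = np.zeros(n + 1)
        for x in np.nonzero(pmf)[0]:
            ks = np.arange(0, min(x, s) + 1)
            new[ks] += pmf[x] * sps.hypergeom.pmf(ks, n, x, s)
        pmf = new
    p = float(min(1.0, pmf[observed_k:].sum()))
    expected = n * float(np.prod([s / n for s in sizes]))
    return TestResult(float(observed_k), p, estimate=expected,
                      method="multiset_intersection")


def arcsine_sqrt(p):
    """Variance-stabilizing transform asin(sqrt(p)) for proportions."""
    arr = np.asarray(p, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("proportions must be in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def holm_adjust(p: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    p = np.asarray(p, float)
    return multipletests(p, method="holm")[1]


def pairwise_group_comparison(values: Sequence[float],
                              groups: Sequence[str],
                              adjust: str = "holm") -> list[PairwiseComparison]:
    """All pairwise Welch t-tests between groups with Holm adjustment."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    levels = sorted(set(groups))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    pairs = list(itertools.combinations(levels, 2))
    raw = []
    for a, b in pairs:
        res = welch_t_test(values[groups == a], values[groups == b])
        raw.append(res)
    if adjust == "holm":
        adj = holm_adjust([r.p for r in raw])
    elif adjust is None or adjust == "none":
        adj = np.array([r.p for r in raw])
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return [
        PairwiseComparison(a, b, r.statistic, r.p, float(pa), r.estimate)
        for (a, b), r, pa in zip(pairs, raw, adj)
    ]
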