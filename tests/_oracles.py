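"""Independent brute-force / closed-form oracles used by the test suite.

Everything here is deliberately naive (enumeration, exact fractions, hand
formulas) and shares no code with the implementation it checks.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np


def enumerate_intersection_counts(n: int, sizes: list[int]) -> np.ndarray:
    """Distribution of |S_1 ∩ ... ∩ S_m| by exhaustive enumeration.

    All sets are independent uniform draws of fixed size from {0..n-1}.
    By symmetry (the joint distribution is invariant under relabeling the
    background), the first set can be fixed to {0..s_1-1}; the remaining
    sets are enumerated exhaustively as bitmasks.  Returns the pmf as
    counts normalised to probabilities, indexed by intersection size.
    """
    first = (1 << sizes[0]) - 1
    rest_masks = []
    for s in sizes[1:]:
        rest_masks.append([
            sum(1 << i for i in combo)
            for combo in itertools.combinations(range(n), s)
        ])
    counts = np.zeros(min(sizes) + 1)
    for combo in itertools.product(*rest_masks):
        inter = first
        for m in combo:
            inter &= m
        counts[inter.bit_count()] += 1
    return counts / counts.sum()


def enumerate_intersection_tail(n: int, sizes: list[int], k: int) -> float:
    """P(|S_1 ∩ ... ∩ S_m| >= k) by exhaustive enumeration.

    All sets are independent uniform draws of fixed size from {0..n-1}.
    By symmetry (the joint distribution is invariant under relabeling the
    background), the first set can be fixed to {0..s_1-1}; the remaining
    sets are enumerated exhaustively as bitmasks.
    """
    first = (1 << sizes[0]) - 1
    rest_masks = []
    for s in sizes[1:]:
        rest_masks.append([
            sum(1 << i for i in combo)
            for combo in itertools.combinations(range(n), s)
        ])
    hits = 0
    total = 0
    for combo in itertools.product(*rest_masks):
        inter = first
        for m in combo:
            inter &= m
        total += 1
        if inter.bit_count() >= k:
            hits += 1
    return hits / total


def fisher_two_sided_exact(table) -> Fraction:
    """Two-sided Fisher p by exact-fraction hypergeometric enumeration.

    Sums the probabilities of all outcomes with the observed margins whose
    probability does not exceed the observed outcome's (the convention of
    summing "as or more extreme by likelihood").
    """
    from math import comb

    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = prob(a)
    total = Fraction(0)
    for x in range(lo, hi + 1):
        p = prob(x)
        if p <= p_obs:
            total += p
    return total


def chi_square_expected_formula(table) -> float:
    """Pearson chi-square from the expected-count definition."""
    t = np.asarray(table, dtype=float)
    row = t.sum(axis=1, keepdims=True)
    col = t.sum(axis=0, keepdims=True)
    expected = row * col / t.sum()
    return float(((t - expected) ** 2 / expected).sum())


def one_way_anova_hand(y, groups):
    """One-way ANOVA (SS_between, SS_within, F) from the textbook sums."""
    y = np.asarray(y, float)
    groups = np.asarray(groups)
    grand = y.mean()
    ss_b = ss_w = 0.0
    for g in set(groups):
        sub = y[groups == g]
        ss_b += len(sub) * (sub.mean() - grand) ** 2
        ss_w += ((sub - sub.mean()) ** 2).sum()
    df_b = len(set(groups)) - 1
    df_w = len(y) - len(set(groups))
    f = (ss_b / df_b) / (ss_w / df_w) if ss_w > 0 else np.nan
    return ss_b, ss_w, f


def average_ranks(x):
    """Average (midrank) ranks computed by explicit enumeration."""
    x = list(x)
    ranks = []
    for xi in x:
        less = sum(1 for xj in x if xj < xi)
        equal = sum(1 for xj in x if xj == xi)
        ranks.append(less + (equal + 1) / 2)
    return np.asarray(ranks, float)


def holm_stepdown(p):
    """Holm step-down adjustment computed directly from the definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def bh_stepup(p):
    """Benjamini-Hochberg step-up adjustment from the definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    current = 1.0
    for rank in range(m - 1, -1, -1):
        idx = order[rank]
        current = min(current, p[idx] * m / (rank + 1))
        adj[idx] = current
    return adj
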