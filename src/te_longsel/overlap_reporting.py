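"""Cross-study sharing of regime-classified TE families.

The background for every overlap test is the set of families retained in
*all* compared studies — a family that cannot be observed in a study cannot
be called in it — and the significance of an observed intersection is
assessed with the exact multi-set intersection test of
:mod:`te_longsel.stats_core`.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .abundance import LABEL_C, LABEL_S, RegimeClassification
from . import stats_core as st

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapResult:
    """Intersection of one family group across one subset of studies."""

    studies: tuple[str, ...]
    group: str
    intersection: tuple[str, ...]
    set_sizes: tuple[int, ...]
    background_size: int
    p: float

    @property
    def k(self) -> int:
        return len(self.intersection)

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def cross_study_overlaps(classifications: Mapping[str, Sequence[RegimeClassification]],
                         background: Sequence[str]) -> list[OverlapResult]:
    """Overlap significance for every subset of >= 2 studies and each group.

    Group sets are restricted to the common background before intersecting;
    an empty group in any member study yields k = 0, p = 1.
    """
    studies = sorted(classifications)
    if len(studies) < 2:
        raise ValueError("need at least two studies")
    bg = set(background)
    n = len(bg)
    sets: dict[tuple[str, str], set[str]] = {}
    for study in studies:
        for group in (LABEL_S, LABEL_C):
            sets[(study, group)] = {
                c.family for c in classifications[study]
                if c.label == group and c.family in bg}
    results = []
    for m in range(2, len(studies) + 1):
        for combo in itertools.combinations(studies, m):
            for group in (LABEL_S, LABEL_C):
                member_sets = [sets[(s, group)] for s in combo]
                sizes = tuple(len(s) for s in member_sets)
                inter = set.intersection(*member_sets)
                if min(sizes) == 0:
                    p = 1.0
                else:
                    p = st.multiset_intersection_test(
                        n, sizes, len(inter)).p
                results.append(OverlapResult(
                    studies=combo, group=group,
                    intersection=tuple(sorted(inter)), set_sizes=sizes,
                    background_size=n, p=p))
    return results


def pairwise_fc_correlation(classifications: Mapping[str, Sequence[RegimeClassification]]
                            ) -> dict[tuple[str, str], st.TestResult | None]:
    """Spearman correlation of log2 fold changes between study pairs."""
    studies = sorted(classifications)
    fc = {s: {c.family: c.log2fc for c in classifications[s]
              if not math.isnan(c.log2fc)}
          for s in studies}
    out: dict[tuple[str, str], st.TestResult | None] = {}
    for a, b in itertools.combinations(studies, 2):
        shared = sorted(set(fc[a]) & set(fc[b]))
        if len(shared) < 3:
            logger.warning("pairwise_fc_correlation: <3 shared families "
                           "for %s-%s", a, b)
            out[(a, b)] = None
            continue
        out[(a, b)] = st.rank_correlation(
            [fc[a][f] for f in shared], [fc[b][f] for f in shared])
    return out


def te_vs_gene_proportions(te_counts: Sequence[int],
                           gene_counts: Sequence[int]) -> st.TestResult:
    """Chi-square comparison of up/down/unchanged proportions for TE
    families versus genes (a 2 x 3 contingency table).

    Categories empty in both rows are dropped with a log message.
    """
    te = np.asarray(te_counts, int)
    gene = np.asarray(gene_counts, int)
    if te.shape != (3,) or gene.shape != (3,):
        raise ValueError("expect three categories: up, down, unchanged")
    keep = (te + gene) > 0
    if not keep.all():
        logger.info("te_vs_gene_proportions: dropped %d empty categories",
                    int((~keep).sum()))
    return st.chi_square_contingency(np.vstack([te[keep], gene[keep]]))


def overlaps_to_frame(results: Sequence[OverlapResult]) -> pd.DataFrame:
    """Tabular rendering of overlap results (one row per subset x group)."""
    return pd.DataFrame([
        {
            "studies": "+".join(r.studies), "group": r.group,
            "k": r.k, "set_sizes": ",".join(map(str, r.set_sizes)),
            "background": r.background_size, "p": r.p,
            "significant": r.significant,
            "families": ",".join(r.intersection),
        }
        for r in results
    ])
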