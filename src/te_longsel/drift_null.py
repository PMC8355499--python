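"""Wright–Fisher drift null for the S>C : C>S family imbalance.

Each TE family starts from a shared frequency ``p0`` (its average
segregating frequency in a deeply sequenced reference population) and every
replicate population evolves independently by neutral binomial resampling
of ``2 Ne`` chromosomes per generation, with 0 and 1 absorbing — no
mutation and no new transposition, so the null is drift-only by
construction.  Control lineages evolve for ``gen_control`` generations at
``ne_control``; selected lineages for ``gen_selected`` generations at
``ceil(ne_selected * breeding_fraction_selected)``, the breeding fraction
capturing that only part of a late-breeding population may still reproduce
at old age.

Each simulated data set is classified exactly like the observed one: a
family is S>C when its selected-replicate mean exceeds its control mean
(strictly; exact ties count for neither side), plus the stricter
consistency variant (all-pairwise dominance, as in abundance approach #3).
The neutrality p-value is the fraction of simulations whose S>C proportion
reaches the observed one.

Randomness uses one substream per simulation index derived from the master
seed, so enlarging ``n_sims`` extends — never reshuffles — earlier runs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
import numpy as np

logger = logging.getLogger(__name__)

MODE_FAMILY_MEAN = "family_mean"
MODE_PER_SITE = "per_site"

_STREAM_SIM = 7


@dataclass
class DriftSimConfig:
    """Demography and bookkeeping for one batch of drift simulations."""

    start_freqs: np.ndarray
    ne_control: int
    ne_selected: int
    gen_control: int
    gen_selected: int
    n_rep_control: int = 2
    n_rep_selected: int = 2
    breeding_fraction_selected: float = 1.0
    n_sims: int = 5000
    mode: str = MODE_FAMILY_MEAN
    n_sites: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.start_freqs = np.asarray(self.start_freqs, dtype=float)
        if ((self.start_freqs < 0) | (self.start_freqs > 1)).any():
            raise ValueError("start frequencies must be in [0, 1]")
        if min(self.ne_control, self.ne_selected) <= 0:
            raise ValueError("Ne must be > 0")
        if min(self.gen_control, self.gen_selected) < 0:
            raise ValueError("generations must be >= 0")
        if min(self.n_rep_control, self.n_rep_selected) < 1:
            raise ValueError("need at least one replicate per regime")
        if not 0 < self.breeding_fraction_selected <= 1:
            raise ValueError("breeding fraction must be in (0, 1]")
        if self.mode not in (MODE_FAMILY_MEAN, MODE_PER_SITE):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == MODE_PER_SITE:
            if self.n_sites is None:
                raise ValueError("per_site mode requires n_sites")
            self.n_sites = np.asarray(self.n_sites, dtype=int)
            if len(self.n_sites) != len(self.start_freqs):
                raise ValueError("n_sites must match start_freqs")
            if (self.n_sites < 1).any():
                raise ValueError("n_sites must be >= 1")

    @property
    def ne_selected_effective(self) -> int:
        return max(1, math.ceil(self.ne_selected
                                * self.breeding_fraction_selected))

    @property
    def n_families(self) -> int:
        return len(self.start_freqs)


@dataclass
class DriftSimResult:
    """Per-simulation family counts plus the empirical neutrality p-value."""

    count_sgtc: np.ndarray
    count_cgts: np.ndarray
    consistent_sgtc: np.ndarray
    consistent_cgts: np.ndarray
    observed_statistic: float
    statistic_name: str
    p_value: float
    n_sims_used: int
    n_excluded: int

    @property
    def simulated_statistics(self) -> np.ndarray:
        return _statistic(self.count_sgtc, self.count_cgts,
                          self.statistic_name)


def wf_trajectory(p0: float, ne: int, generations: int,
                  rng: np.random.Generator) -> float:
    """Final frequency after ``generations`` of binomial resampling."""
    if not 0 <= p0 <= 1:
        raise ValueError("p0 must be in [0, 1]")
    p = float(p0)
    for _ in range(generations):
        if p in (0.0, 1.0):  # absorbing
            break
        p = rng.binomial(2 * ne, p) / (2 * ne)
    return p


def _evolve(p: np.ndarray, ne: int, generations: int,
            rng: np.random.Generator) -> np.ndarray:
    out = p.astype(float).copy()
    two_ne = 2 * ne
    for _ in range(generations):
        out = rng.binomial(two_ne, out) / two_ne
    return out


def _simulate_one(config: DriftSimConfig, rng: np.random.Generator
                  ) -> tuple[np.ndarray, np.ndarray]:
    """One simulated data set: final values, shapes (n_fam, reps)."""
    p0 = config.start_freqs
    if config.mode == MODE_FAMILY_MEAN:
        s0 = np.repeat(p0[:, None], config.n_rep_selected, axis=1)
        c0 = np.repeat(p0[:, None], config.n_rep_control, axis=1)
        s = _evolve(s0, config.ne_selected_effective, config.gen_selected, rng)
        c = _evolve(c0, config.ne_control, config.gen_control, rng)
        return s, c
    # per_site: every site of a family drifts independently; the family's
    # abundance proxy is the mean site frequency
    sites0 = np.repeat(p0, config.n_sites)
    edges = np.concatenate([[0], np.cumsum(config.n_sites)])
    s0 = np.repeat(sites0[:, None], config.n_rep_selected, axis=1)
    c0 = np.repeat(sites0[:, None], config.n_rep_control, axis=1)
    s = _evolve(s0, config.ne_selected_effective, config.gen_selected, rng)
    c = _evolve(c0, config.ne_control, config.gen_control, rng)
    s_fam = np.add.reduceat(s, edges[:-1], axis=0) / config.n_sites[:, None]
    c_fam = np.add.reduceat(c, edges[:-1], axis=0) / config.n_sites[:, None]
    return s_fam, c_fam


def simulate_design(config: DriftSimConfig
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Simulate ``n_sims`` data sets.

    Returns arrays of shape (n_sims, n_families, n_replicates) for the
    selected and control regimes.
    """
    s_all = np.empty((config.n_sims, config.n_families,
                      config.n_rep_selected))
    c_all = np.empty((config.n_sims, config.n_families,
                      config.n_rep_control))
    for i in range(config.n_sims):
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, _STREAM_SIM, i]))
        s_all[i], c_all[i] = _simulate_one(config, rng)
    return s_all, c_all


def classify_simulation(s: np.ndarray, c: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray,
                                   np.ndarray, np.ndarray]:
    """Count S>C / C>S families per simulation, mean- and consistency-based.

    Accepts (n_fam, reps) for one simulation or (n_sims, n_fam, reps);
    returns arrays over simulations (scalars become length-1 arrays).
    Exact ties of the replicate means count for neither side.
    """
    s = np.asarray(s, float)
    c = np.asarray(c, float)
    if s.ndim == 2:
        s = s[None]
    if c.ndim == 2:
        c = c[None]
    if s.shape[0] != c.shape[0]:
        raise ValueError("regime arrays disagree on n_sims")
    ms, mc = s.mean(axis=2), c.mean(axis=2)
    count_sgtc = (ms > mc).sum(axis=1)
    count_cgts = (mc > ms).sum(axis=1)
    consistent_sgtc = (s.min(axis=2) > c.max(axis=2)).sum(axis=1)
    consistent_cgts = (c.min(axis=2) > s.max(axis=2)).sum(axis=1)
    return count_sgtc, count_cgts, consistent_sgtc, consistent_cgts


def _statistic(sgtc: np.ndarray, cgts: np.ndarray, name: str) -> np.ndarray:
    sgtc = np.asarray(sgtc, float)
    cgts = np.asarray(cgts, float)
    denom = sgtc + cgts if name == "proportion" else cgts
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, sgtc / np.where(denom > 0, denom, 1),
                       np.nan)
    return out


def neutrality_pvalue(config: DriftSimConfig, observed_sgtc: int,
                      observed_cgts: int, statistic: str = "proportion",
                      plus_one: bool = False) -> DriftSimResult:
    """Empirical p-value for the observed S>C : C>S imbalance under drift.

    ``statistic="proportion"`` uses S>C / (S>C + C>S) (tied families are
    excluded from the denominator); ``"ratio"`` uses S>C / C>S.  The
    p-value is the fraction of simulations whose statistic is at least the
    observed one; ``plus_one`` applies the (r+1)/(n+1) correction.
    Simulations with a zero denominator are excluded and counted.
    """
    if statistic not in ("proportion", "ratio"):
        raise ValueError(f"unknown statistic {statistic!r}")
    obs = _statistic(np.array([observed_sgtc]),
                     np.array([observed_cgts]), statistic)[0]
    if math.isnan(obs):
        raise ValueError("observed statistic undefined (both counts zero)")
    s, c = simulate_design(config)
    sgtc, cgts, cons_s, cons_c = classify_simulation(s, c)
    stats = _statistic(sgtc, cgts, statistic)
    valid = ~np.isnan(stats)
    n_excluded = int((~valid).sum())
    n_used = int(valid.sum())
    if n_used == 0:
        raise ValueError("degenerate configuration (no drift?): "
                         "all simulations have empty denominators")
    if n_excluded:
        logger.info("neutrality_pvalue: excluded %d simulations with "
                    "zero denominator", n_excluded)
    r = int((stats[valid] >= obs).sum())
    p = (r + 1) / (n_used + 1) if plus_one else r / n_used
    return DriftSimResult(
        count_sgtc=sgtc, count_cgts=cgts,
        consistent_sgtc=cons_s, consistent_cgts=cons_c,
        observed_statistic=float(obs), statistic_name=statistic,
        p_value=float(p), n_sims_used=n_used, n_excluded=n_excluded,
    )
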