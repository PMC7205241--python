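"""Three-state partitioned-survival cohort engine.

State occupancies at each cycle boundary are read directly off the two
fitted curves: PFS occupancy is S_PFS(t_u), the dead fraction is
1 - S_OS(t_u), and the progressed-disease (PD) fraction is the difference
S_OS - S_PFS (clamped at zero should the curves cross).  Per-cycle totals
(life-years, QALYs, state costs) are accumulated with an optional
trapezoid half-cycle correction, treating transitions as occurring
mid-cycle on average.

A per-cycle Markov formulation driven by the conditional stay/event
probabilities is provided as a cross-check engine; because everyone alive
faces the overall-survival event probability, its occupancies telescope
back to the partitioned-survival trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ModelConfig
from .survival import LogLogisticParams, event_probability, survival_probability

logger = logging.getLogger(__name__)


class TraceError(ValueError):
    """Raised when the survival curves are inconsistent with the state model."""


@dataclass(frozen=True)
class UtilitySet:
    """Health-state utilities (per year of occupancy)."""

    u_pfs: float = 0.68
    u_pd: float = 0.42
    u_dead: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.u_pd <= self.u_pfs <= 1.0):
            raise ValueError(
                f"utilities must satisfy 0 <= u_pd <= u_pfs <= 1, got "
                f"u_pfs={self.u_pfs}, u_pd={self.u_pd}"
            )
        if self.u_dead != 0.0:
            raise ValueError("utility of death must be 0")


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state occupancy and discount weights, cycles 0..n_cycles."""

    t_months: np.ndarray
    pfs: np.ndarray
    pd: np.ndarray
    dead: np.ndarray
    discount: np.ndarray
    n_clamped: int = 0

    @property
    def n_cycles(self) -> int:
        return len(self.t_months) - 1

    @property
    def alive(self) -> np.ndarray:
        return self.pfs + self.pd

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(len(self.t_months)),
                "t_months": self.t_months,
                "occ_pfs": self.pfs,
                "occ_pd": self.pd,
                "occ_dead": self.dead,
                "discount_weight": self.discount,
            }
        )


def build_trace(
    pfs: LogLogisticParams,
    os: LogLogisticParams,
    cfg: ModelConfig,
    max_clamped_fraction: float = 0.05,
) -> CohortTrace:
    """Build the partitioned-survival occupancy trace over the whole horizon.

    PD occupancy S_OS - S_PFS is clamped at zero where negative (crossing
    curves); clamped cycles are counted and more than ``max_clamped_fraction``
    of them raises :class:`TraceError`.
    """
    u = np.arange(cfg.n_cycles + 1)
    t = cfg.months_at(u)
    s_pfs = survival_probability(pfs, t)
    s_os = survival_probability(os, t)
    pd_raw = s_os - s_pfs
    clamped = pd_raw < 0
    n_clamped = int(clamped.sum())
    if n_clamped:
        logger.warning(
            "PD occupancy clamped to 0 at %d of %d cycles (curves cross)",
            n_clamped,
            len(u),
        )
        if n_clamped > max_clamped_fraction * len(u):
            raise TraceError(
                f"PFS curve exceeds OS curve at {n_clamped}/{len(u)} cycles; "
                "the two fits are inconsistent with a partitioned survival model"
            )
    occ_pd = np.where(clamped, 0.0, pd_raw)
    occ_pfs = np.where(clamped, s_os, s_pfs)  # keep occupancies summing to 1
    return CohortTrace(
        t_months=t,
        pfs=occ_pfs,
        pd=occ_pd,
        dead=1.0 - s_os,
        discount=cfg.discount_factor(u),
        n_clamped=n_clamped,
    )


def build_trace_markov(
    pfs: LogLogisticParams, os: LogLogisticParams, cfg: ModelConfig
) -> CohortTrace:
    """Cross-check engine: per-cycle Markov recursion from Eq-style probabilities.

    Everyone alive faces the overall-survival event probability for the cycle;
    those event-free w.r.t. the PFS curve remain in PFS, the remaining alive
    mass sits in PD.
    """
    n = cfg.n_cycles
    occ_pfs = np.empty(n + 1)
    occ_pd = np.empty(n + 1)
    dead = np.empty(n + 1)
    occ_pfs[0], occ_pd[0], dead[0] = 1.0, 0.0, 0.0
    alive, in_pfs = 1.0, 1.0
    for u in range(n):
        alive *= 1.0 - event_probability(os, u, cfg)
        in_pfs *= 1.0 - event_probability(pfs, u, cfg)
        in_pfs_c = min(in_pfs, alive)
        occ_pfs[u + 1] = in_pfs_c
        occ_pd[u + 1] = alive - in_pfs_c
        dead[u + 1] = 1.0 - alive
    return CohortTrace(
        t_months=cfg.months_at(np.arange(n + 1)),
        pfs=occ_pfs,
        pd=occ_pd,
        dead=dead,
        discount=cfg.discount_factor(np.arange(n + 1)),
    )


def cycle_weights(values: np.ndarray, cfg: ModelConfig) -> np.ndarray:
    """Per-cycle contributions of a boundary-valued stream, length n_cycles.

    Trapezoid (half-cycle corrected) averaging of adjacent boundaries when
    enabled, otherwise the left-endpoint value.
    """
    v = np.asarray(values, dtype=float)
    if cfg.half_cycle_correction:
        return 0.5 * (v[:-1] + v[1:])
    return v[:-1]


def state_cycle_total(
    trace: CohortTrace, occupancy: np.ndarray, cfg: ModelConfig, discounted: bool
) -> float:
    """Accumulated (optionally discounted) person-cycles of an occupancy stream."""
    stream = occupancy * trace.discount if discounted else occupancy
    return float(cycle_weights(stream, cfg).sum())


def life_years(trace: CohortTrace, cfg: ModelConfig) -> float:
    """Life-years over the horizon: alive person-cycles times cycle length.

    Undiscounted unless ``cfg.discount_life_years`` is set.
    """
    total_cycles = state_cycle_total(trace, trace.alive, cfg, cfg.discount_life_years)
    return total_cycles * cfg.cycle_years


def quality_adjusted_life_years(
    trace: CohortTrace, utilities: UtilitySet, cfg: ModelConfig
) -> float:
    """Discounted QALYs: utility-weighted occupancy, half-cycle corrected."""
    stream = (utilities.u_pfs * trace.pfs + utilities.u_pd * trace.pd) * trace.discount
    return float(cycle_weights(stream, cfg).sum()) * cfg.cycle_years
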