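"""Incremental cost-effectiveness analysis and value-based pricing.

A :class:`ModelBundle` carries everything needed to evaluate one strategy
pair: survival parameters per arm/endpoint, economic inputs, utilities and
the time-grid configuration.  :func:`evaluate_strategy` runs one arm end to
end (trace -> outcomes -> costs); :func:`compare` forms increments, ICERs
and net monetary benefit; :func:`threshold_price` inverts the monotone
price -> ICER map to find the value-based ramucirumab price at a
willingness-to-pay threshold, by bisection with a closed-form cross-check
(the ICER is affine in the per-cycle price, with slope equal to the
discounted ramucirumab-treated cycle count over the QALY increment).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .cohort import (
    CohortTrace,
    UtilitySet,
    build_trace,
    cycle_weights,
    life_years,
    quality_adjusted_life_years,
)
from .config import ModelConfig
from .costing import AEProfile, CostBreakdown, CostInputs, DosingSpec, strategy_cost
from .survival import LogLogisticParams
from . import fixtures

ICER_QALY_TOL = 1e-9  # |delta QALY| below this -> ICER undefined


class ThresholdError(ValueError):
    """Raised when a threshold-price bracket does not straddle the target WTP."""


@dataclass(frozen=True)
class WTPThreshold:
    """A willingness-to-pay threshold in $ per QALY."""

    label: str
    usd_per_qaly: float

    def __post_init__(self) -> None:
        if self.usd_per_qaly <= 0:
            raise ValueError("WTP threshold must be positive")


@dataclass(frozen=True)
class StrategyResult:
    label: str
    cost: float  # total discounted cost, $
    life_years: float
    qalys: float
    breakdown: CostBreakdown | None = None
    trace: CohortTrace | None = None


@dataclass(frozen=True)
class CEAComparison:
    """Increments of intervention minus comparator, with ICERs and NMB."""

    delta_cost: float
    delta_ly: float
    delta_qaly: float
    icer_per_qaly: float | None
    icer_per_ly: float | None
    nmb: float
    wtp: float
    dominance: str | None = None  # "dominant" | "dominated" | None

    @property
    def icer_defined(self) -> bool:
        return self.icer_per_qaly is not None


@dataclass(frozen=True)
class ModelBundle:
    """All inputs for a two-arm model evaluation."""

    survival: dict[tuple[str, str], LogLogisticParams]
    costs: CostInputs
    dosing: DosingSpec
    ae_profiles: dict[str, AEProfile]
    utilities: UtilitySet
    config: ModelConfig

    def with_ram_price(self, price_per_cycle: float) -> "ModelBundle":
        return replace(self, costs=self.costs.with_ram_price_per_cycle(price_per_cycle))

    def with_(self, **kwargs) -> "ModelBundle":
        return replace(self, **kwargs)


def default_bundle(ram_price_per_cycle: float = 244.0) -> ModelBundle:
    """The baseline model: published survival/economic inputs, price as given."""
    return ModelBundle(
        survival={
            key: fixtures.survival_params(*key) for key in fixtures.SURVIVAL_PARAMS
        },
        costs=fixtures.default_costs(ram_price_per_cycle=ram_price_per_cycle),
        dosing=fixtures.default_dosing(),
        ae_profiles={arm: fixtures.default_ae_profile(arm) for arm in ("ram", "pla")},
        utilities=fixtures.default_utilities(),
        config=fixtures.default_config(),
    )


def evaluate_strategy(bundle: ModelBundle, arm: str) -> StrategyResult:
    """Run one arm end to end: occupancy trace, LY/QALY, discounted cost."""
    trace = build_trace(
        bundle.survival[(arm, "pfs")], bundle.survival[(arm, "os")], bundle.config
    )
    breakdown = strategy_cost(
        trace, bundle.dosing, bundle.costs, bundle.ae_profiles[arm], bundle.config, arm
    )
    return StrategyResult(
        label=arm,
        cost=breakdown.total,
        life_years=life_years(trace, bundle.config),
        qalys=quality_adjusted_life_years(trace, bundle.utilities, bundle.config),
        breakdown=breakdown,
        trace=trace,
    )


def compare(
    intervention: StrategyResult,
    comparator: StrategyResult,
    wtp: WTPThreshold | float,
) -> CEAComparison:
    """Incremental analysis of intervention vs comparator at one WTP."""
    wtp_val = wtp.usd_per_qaly if isinstance(wtp, WTPThreshold) else float(wtp)
    d_cost = intervention.cost - comparator.cost
    d_ly = intervention.life_years - comparator.life_years
    d_qaly = intervention.qalys - comparator.qalys
    if abs(d_qaly) < ICER_QALY_TOL:
        icer_q = None
    else:
        icer_q = d_cost / d_qaly
    icer_ly = d_cost / d_ly if abs(d_ly) >= ICER_QALY_TOL else None
    dominance = None
    if d_qaly > 0 and d_cost < 0:
        dominance = "dominant"
    elif d_qaly < 0 and d_cost > 0:
        dominance = "dominated"
    return CEAComparison(
        delta_cost=d_cost,
        delta_ly=d_ly,
        delta_qaly=d_qaly,
        icer_per_qaly=icer_q,
        icer_per_ly=icer_ly,
        nmb=wtp_val * d_qaly - d_cost,
        wtp=wtp_val,
        dominance=dominance,
    )


def run_comparison(
    bundle: ModelBundle, wtp: WTPThreshold | float
) -> tuple[StrategyResult, StrategyResult, CEAComparison]:
    """Evaluate both arms and compare (ram vs pla)."""
    ram = evaluate_strategy(bundle, "ram")
    pla = evaluate_strategy(bundle, "pla")
    return ram, pla, compare(ram, pla, wtp)


def price_sweep(
    bundle: ModelBundle, price_grid: Sequence[float], wtp: WTPThreshold | float
) -> list[tuple[float, CEAComparison]]:
    """One full two-arm evaluation per ramucirumab price on the grid."""
    if len(price_grid) == 0:
        raise ValueError("price grid must be non-empty")
    if any(p < 0 for p in price_grid):
        raise ValueError("prices must be non-negative")
    out = []
    for price in price_grid:
        _, _, cmp_ = run_comparison(bundle.with_ram_price(price), wtp)
        out.append((float(price), cmp_))
    return out


def ram_cycle_count(bundle: ModelBundle) -> float:
    """Discounted, half-cycle-corrected ramucirumab-treated cycle count.

    This is the slope of the incremental-cost-vs-price line: each extra
    dollar of per-cycle price adds this many discounted dollars of cost.
    """
    trace = build_trace(
        bundle.survival[("ram", "pfs")], bundle.survival[("ram", "os")], bundle.config
    )
    return float(cycle_weights(trace.pfs * trace.discount, bundle.config).sum())


def threshold_price_closed_form(bundle: ModelBundle, wtp: WTPThreshold | float) -> float:
    """Invert the affine price -> ICER map analytically.

    ICER(p) = (dC0 + K p) / dQ with K the discounted RAM-treated cycle
    count, so p* = (wtp * dQ - dC0) / K.  May be negative when even a free
    drug is not cost-effective at the given threshold.
    """
    wtp_val = wtp.usd_per_qaly if isinstance(wtp, WTPThreshold) else float(wtp)
    _, _, at_zero = run_comparison(bundle.with_ram_price(0.0), wtp_val)
    if at_zero.delta_qaly <= 0:
        raise ThresholdError("QALY increment is not positive; no threshold price exists")
    slope = ram_cycle_count(bundle)
    return (wtp_val * at_zero.delta_qaly - at_zero.delta_cost) / slope


def threshold_price(
    bundle: ModelBundle,
    wtp: WTPThreshold | float,
    bracket: tuple[float, float] = (0.0, 5000.0),
    tol: float = 0.01,
    max_iter: int = 200,
) -> float:
    """Value-based per-cycle ramucirumab price at which ICER equals the WTP.

    Bisection on the monotone price -> ICER map within ``bracket`` (which may
    include negative prices for the algebraic inverse), to a price tolerance
    of ``tol`` dollars; the result is cross-checked against the closed-form
    inversion.

    Raises
    ------
    ThresholdError
        If the bracket does not straddle the target WTP.
    """
    wtp_val = wtp.usd_per_qaly if isinstance(wtp, WTPThreshold) else float(wtp)
    lo, hi = bracket
    if lo >= hi:
        raise ValueError("bracket must satisfy low < high")

    def icer_at(price: float) -> float:
        _, _, cmp_ = run_comparison(bundle.with_ram_price(price), wtp_val)
        if cmp_.icer_per_qaly is None:
            raise ThresholdError("ICER undefined (QALY increment ~ 0)")
        return cmp_.icer_per_qaly

    f_lo, f_hi = icer_at(lo) - wtp_val, icer_at(hi) - wtp_val
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if f_lo * f_hi > 0:
        raise ThresholdError(
            f"bracket {bracket} does not straddle WTP {wtp_val:.2f}: "
            f"ICER({lo}) = {f_lo + wtp_val:.2f}, ICER({hi}) = {f_hi + wtp_val:.2f}"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = icer_at(mid) - wtp_val
        if f_mid == 0.0 or (hi - lo) / 2 < tol:
            lo = hi = mid
            break
        if f_lo * f_mid < 0:
            hi = mid
        else:
            lo, f_lo = mid, f_mid
    price = 0.5 * (lo + hi)
    closed = threshold_price_closed_form(bundle, wtp_val)
    if abs(price - closed) > max(10 * tol, 1e-6 * abs(closed)):
        raise ThresholdError(
            f"bisection ({price:.4f}) and closed form ({closed:.4f}) disagree"
        )
    return price
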