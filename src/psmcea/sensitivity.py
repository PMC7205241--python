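"""Deterministic (tornado) and probabilistic sensitivity analysis.

Probabilistic analysis samples every economic parameter from a
moment-matched distribution (lognormal for costs, weight and body surface
area; beta for adverse-event risks and utilities; the discount rate is
held fixed), with mean equal to the baseline and standard error 10% of
the mean by default.  Each of the n iterations re-runs the full two-arm
model; survival parameters carry no published uncertainty and stay fixed,
so the sampled cloud reflects economic-parameter uncertainty only.

One-way analysis moves each parameter to the low and high end of its
published range with everything else at baseline and records the ICER
swing (tornado bars, widest first).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import fixtures
from .cea import ModelBundle, WTPThreshold, run_comparison
from .cohort import UtilitySet
from .costing import AEProfile, CostInputs, DosingSpec

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------- #
# parameter distributions
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class ParamDistribution:
    """Sampling specification for one scalar model parameter.

    ``spread`` is the standard error; when None it defaults to 10% of the
    mean.  ``low``/``high`` bound the one-way (tornado) analysis only.
    """

    name: str
    family: str  # "lognormal" | "beta" | "fixed"
    mean: float
    spread: float | None = None
    low: float | None = None
    high: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "beta", "fixed"):
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.low is not None and self.high is not None:
            if not (self.low <= self.mean <= self.high):
                raise ValueError(
                    f"{self.name}: mean {self.mean} outside range "
                    f"[{self.low}, {self.high}]"
                )

    @property
    def se(self) -> float:
        return 0.1 * self.mean if self.spread is None else self.spread


def make_distribution(spec: ParamDistribution) -> Callable[[np.random.Generator, int], np.ndarray]:
    """Build a moment-matched sampler ``f(rng, size) -> draws``.

    beta:      alpha = m (m(1-m)/s^2 - 1), beta = (1-m)(m(1-m)/s^2 - 1)
    lognormal: sigma^2 = ln(1 + s^2/m^2), mu = ln m - sigma^2/2
    fixed:     every draw equals the mean.
    """
    m, s = spec.mean, spec.se
    if spec.family == "fixed" or s == 0.0:
        return lambda rng, size: np.full(size, m)
    if spec.family == "beta":
        if not 0.0 < m < 1.0:
            raise ValueError(f"{spec.name}: beta mean must be in (0, 1), got {m}")
        if s * s >= m * (1.0 - m):
            raise ValueError(
                f"{spec.name}: beta variance {s*s:.3g} >= m(1-m) = {m*(1-m):.3g}"
            )
        nu = m * (1.0 - m) / (s * s) - 1.0
        a, b = m * nu, (1.0 - m) * nu
        return lambda rng, size: rng.beta(a, b, size)
    if spec.family == "lognormal":
        if m <= 0:
            raise ValueError(f"{spec.name}: lognormal mean must be positive, got {m}")
        sigma2 = math.log1p((s / m) ** 2)
        mu = math.log(m) - sigma2 / 2.0
        sigma = math.sqrt(sigma2)
        return lambda rng, size: rng.lognormal(mu, sigma, size)
    raise AssertionError("unreachable")


def default_distributions(include_weight_bsa: bool = True) -> list[ParamDistribution]:
    """The published sampling scheme over all varied economic parameters."""
    out = []
    for name, (mean, low, high, family) in fixtures.ECONOMIC_PARAMS.items():
        if name == "discount_rate":
            family = "fixed"
        if not include_weight_bsa and name in ("weight_kg", "bsa_m2"):
            family = "fixed"
        out.append(
            ParamDistribution(name=name, family=family, mean=mean, low=low, high=high)
        )
    return out


# --------------------------------------------------------------------------- #
# applying sampled parameter values to a model bundle
# --------------------------------------------------------------------------- #


def apply_overrides(bundle: ModelBundle, values: Mapping[str, float]) -> ModelBundle:
    """Return a bundle with the named economic parameters replaced.

    Recognised names follow :data:`psmcea.fixtures.ECONOMIC_PARAMS`
    (cost_*, risk_<arm>_*, utility_*, weight_kg, bsa_m2, discount_rate).
    The ramucirumab price is not an uncertain parameter and is never touched.
    """
    unknown = set(values) - set(fixtures.ECONOMIC_PARAMS)
    if unknown:
        raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
    costs = bundle.costs
    cost_fields = {
        "cost_pac_per_30mg": "pac_per_30mg",
        "cost_admin_per_unit": "admin_per_unit",
        "cost_lab_per_unit": "lab_per_unit",
        "cost_bsc_per_cycle": "bsc_per_cycle",
        "cost_ct_per_unit": "ct_per_unit",
    }
    cost_updates = {
        attr: values[name] for name, attr in cost_fields.items() if name in values
    }
    ae_costs = dict(costs.ae_episode_costs)
    for name, v in values.items():
        if name.startswith("cost_ae_"):
            key = name.removeprefix("cost_ae_")
            if key not in ae_costs:
                raise KeyError(f"unknown AE cost category {key!r}")
            ae_costs[key] = v
    if cost_updates or any(k.startswith("cost_ae_") for k in values):
        costs = replace(costs, ae_episode_costs=ae_costs, **cost_updates)

    profiles = dict(bundle.ae_profiles)
    for arm in ("ram", "pla"):
        risks = dict(profiles[arm].risks)
        touched = False
        for name, v in values.items():
            if name.startswith(f"risk_{arm}_"):
                key = name.removeprefix(f"risk_{arm}_")
                if key not in risks:
                    raise KeyError(f"unknown AE risk category {key!r}")
                risks[key] = v
                touched = True
        if touched:
            profiles[arm] = AEProfile(risks=risks, arm=arm)

    utilities = bundle.utilities
    if "utility_pfs" in values or "utility_pd" in values:
        utilities = UtilitySet(
            u_pfs=values.get("utility_pfs", utilities.u_pfs),
            u_pd=values.get("utility_pd", utilities.u_pd),
        )

    dosing = bundle.dosing
    dosing_updates = {}
    if "weight_kg" in values:
        dosing_updates["weight_kg"] = values["weight_kg"]
    if "bsa_m2" in values:
        dosing_updates["bsa_m2"] = values["bsa_m2"]
    if dosing_updates:
        dosing = replace(dosing, **dosing_updates)

    config = bundle.config
    if "discount_rate" in values:
        config = config.with_(annual_discount_rate=values["discount_rate"])

    return bundle.with_(
        costs=costs,
        ae_profiles=profiles,
        utilities=utilities,
        dosing=dosing,
        config=config,
    )


# --------------------------------------------------------------------------- #
# probabilistic sensitivity analysis
# --------------------------------------------------------------------------- #


@dataclass
class PSAResult:
    """Monte-Carlo outcome cloud from ``n`` full two-arm evaluations."""

    iterations: pd.DataFrame  # per-iteration sampled params and outcomes
    seed: int
    n_resampled: int
    ram_price_per_cycle: float

    @property
    def n(self) -> int:
        return len(self.iterations)

    @property
    def delta_cost(self) -> np.ndarray:
        return self.iterations["delta_cost"].to_numpy()

    @property
    def delta_qaly(self) -> np.ndarray:
        return self.iterations["delta_qaly"].to_numpy()


def run_psa(
    bundle: ModelBundle,
    distributions: Sequence[ParamDistribution] | None = None,
    n: int = 1000,
    seed: int = 0,
    max_resample: int = 100,
) -> PSAResult:
    """Monte-Carlo parameter uncertainty analysis (deterministic under seed).

    Each iteration draws every varied parameter, enforces the utility
    ordering u_pd <= u_pfs (violating pairs are redrawn and counted), and
    runs both arms through the full model.
    """
    if distributions is None:
        distributions = default_distributions()
    samplers = {d.name: make_distribution(d) for d in distributions}
    rng = np.random.default_rng(seed)
    rows = []
    n_resampled = 0
    for _ in range(n):
        draws = {name: float(f(rng, 1)[0]) for name, f in samplers.items()}
        tries = 0
        while draws.get("utility_pd", 0.0) > draws.get("utility_pfs", 1.0):
            draws["utility_pd"] = float(samplers["utility_pd"](rng, 1)[0])
            draws["utility_pfs"] = float(samplers["utility_pfs"](rng, 1)[0])
            n_resampled += 1
            tries += 1
            if tries > max_resample:
                raise RuntimeError("could not sample ordered utilities")
        ram, pla, cmp_ = run_comparison(apply_overrides(bundle, draws), wtp=0.0)
        rows.append(
            {
                **draws,
                "cost_ram_arm": ram.cost,
                "cost_pla_arm": pla.cost,
                "qaly_ram_arm": ram.qalys,
                "qaly_pla_arm": pla.qalys,
                "delta_cost": cmp_.delta_cost,
                "delta_ly": cmp_.delta_ly,
                "delta_qaly": cmp_.delta_qaly,
            }
        )
    if n_resampled:
        logger.info("resampled %d utility pairs to restore ordering", n_resampled)
    return PSAResult(
        iterations=pd.DataFrame(rows),
        seed=seed,
        n_resampled=n_resampled,
        ram_price_per_cycle=bundle.costs.resolve_ram_price_per_cycle(bundle.dosing),
    )


def acceptability_at(psa: PSAResult, wtp: WTPThreshold | float) -> float:
    """Fraction of iterations with positive net monetary benefit at ``wtp``."""
    if psa.n == 0:
        raise ValueError("empty PSA")
    wtp_val = wtp.usd_per_qaly if isinstance(wtp, WTPThreshold) else float(wtp)
    return float(np.mean(wtp_val * psa.delta_qaly - psa.delta_cost > 0))


def ceac(psa: PSAResult, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a WTP grid."""
    if len(wtp_grid) == 0:
        raise ValueError("WTP grid must be non-empty")
    return pd.DataFrame(
        {
            "wtp": list(wtp_grid),
            "probability_cost_effective": [acceptability_at(psa, w) for w in wtp_grid],
        }
    )


def ceac_by_price(
    bundle: ModelBundle,
    price_grid: Sequence[float],
    wtps: Sequence[WTPThreshold | float],
    n: int = 1000,
    seed: int = 0,
    distributions: Sequence[ParamDistribution] | None = None,
) -> pd.DataFrame:
    """Acceptability vs ramucirumab price, one PSA per price point.

    The same seed is reused at every price (common random numbers), so the
    curves differ only through the price, not through sampling noise.
    """
    rows = []
    for price in price_grid:
        psa = run_psa(
            bundle.with_ram_price(price), distributions=distributions, n=n, seed=seed
        )
        for wtp in wtps:
            wtp_val = wtp.usd_per_qaly if isinstance(wtp, WTPThreshold) else float(wtp)
            rows.append(
                {
                    "ram_price_per_cycle": float(price),
                    "wtp": wtp_val,
                    "probability_cost_effective": acceptability_at(psa, wtp_val),
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------- #
# one-way (tornado) analysis
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low_value: float
    high_value: float
    icer_at_low: float | None
    icer_at_high: float | None
    baseline_icer: float

    @property
    def width(self) -> float:
        ends = [v for v in (self.icer_at_low, self.icer_at_high) if v is not None]
        if len(ends) < 2:
            return math.inf  # truncated bar: undefined ICER at one end
        return abs(ends[1] - ends[0])


RAM_PRICE_TORNADO_FRACTION = 0.5  # +-50% around the scenario price


def tornado(
    bundle: ModelBundle,
    wtp: WTPThreshold | float,
    distributions: Sequence[ParamDistribution] | None = None,
    include_ram_price: bool = True,
) -> list[TornadoEntry]:
    """One-way sensitivity of the ICER to each parameter's published range.

    Each parameter in turn is set to its low and then high bound with all
    others at baseline and the two-arm model is re-run; entries are sorted
    by descending ICER swing.  The ramucirumab per-cycle price (which has
    no published range) is varied +-50% around the scenario price.
    """
    if distributions is None:
        distributions = default_distributions()
    _, _, base = run_comparison(bundle, wtp)
    if base.icer_per_qaly is None:
        raise ValueError("baseline ICER undefined; tornado not meaningful")
    entries: list[TornadoEntry] = []

    def icer_with(values: Mapping[str, float]) -> float | None:
        _, _, cmp_ = run_comparison(apply_overrides(bundle, values), wtp)
        return cmp_.icer_per_qaly

    for dist in distributions:
        if dist.name == "discount_rate":
            lo_hi = (dist.low, dist.high)
        elif dist.low is None or dist.high is None:
            continue
        else:
            lo_hi = (dist.low, dist.high)
        at_low = icer_with({dist.name: lo_hi[0]})
        at_high = icer_with({dist.name: lo_hi[1]})
        if at_low is None or at_high is None:
            warnings.warn(
                f"tornado bar for {dist.name} truncated: ICER undefined at a bound",
                stacklevel=2,
            )
        entries.append(
            TornadoEntry(
                parameter=dist.name,
                low_value=lo_hi[0],
                high_value=lo_hi[1],
                icer_at_low=at_low,
                icer_at_high=at_high,
                baseline_icer=base.icer_per_qaly,
            )
        )

    if include_ram_price:
        base_price = bundle.costs.resolve_ram_price_per_cycle(bundle.dosing)
        lo = base_price * (1 - RAM_PRICE_TORNADO_FRACTION)
        hi = base_price * (1 + RAM_PRICE_TORNADO_FRACTION)

        def icer_at_price(p: float) -> float | None:
            _, _, cmp_ = run_comparison(bundle.with_ram_price(p), wtp)
            return cmp_.icer_per_qaly

        entries.append(
            TornadoEntry(
                parameter="cost_ram_per_cycle",
                low_value=lo,
                high_value=hi,
                icer_at_low=icer_at_price(lo),
                icer_at_high=icer_at_price(hi),
                baseline_icer=base.icer_per_qaly,
            )
        )

    entries.sort(key=lambda e: e.width, reverse=True)
    return entries


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low_value": e.low_value,
                "high_value": e.high_value,
                "icer_at_low": e.icer_at_low,
                "icer_at_high": e.icer_at_high,
                "baseline_icer": e.baseline_icer,
                "width": e.width,
            }
            for e in entries
        ]
    )
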