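"""Strategy costing: drugs, administration, monitoring, supportive care, AEs.

Cost structure (all 2018 USD):

* while progression-free (on treatment): drug acquisition per cycle
  (ramucirumab 8 mg/kg on days 1 and 15 -> 2 infusions; paclitaxel
  80 mg/m^2 on days 1, 8 and 15 -> 3 infusions), administration per
  infusion day, one laboratory panel per cycle, and a CT scan every
  6 weeks (2/3 of a scan per 28-day cycle);
* while in progressed disease: best supportive care per cycle;
* a one-off expected adverse-event management cost at model entry
  (grade-3/4 incidence times episode cost, summed over categories).

State streams are half-cycle corrected and discounted like the health
outcomes; the AE cost is an entry cost and is neither corrected nor
discounted.  Drug quantities are priced continuously per mg (no vial
rounding).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .cohort import CohortTrace, cycle_weights
from .config import ModelConfig

AE_CATEGORIES = (
    "fatigue_appetite",
    "abdominal_pain_diarrhoea",
    "nausea_vomiting",
    "neutropenia",
    "hypertension",
)

CT_INTERVAL_DAYS = 42.0  # radiological follow-up every 6 weeks


class CostingError(ValueError):
    pass


@dataclass(frozen=True)
class DosingSpec:
    """Patient size and per-cycle dosing schedule."""

    weight_kg: float = 65.0
    bsa_m2: float = 1.62
    ram_mg_per_kg: float = 8.0
    ram_infusions_per_cycle: int = 2
    pac_mg_per_m2: float = 80.0
    pac_infusions_per_cycle: int = 3

    def __post_init__(self) -> None:
        if self.weight_kg <= 0 or self.bsa_m2 <= 0:
            raise ValueError("weight and body surface area must be positive")

    @property
    def ram_mg_per_cycle(self) -> float:
        """Total ramucirumab milligrams per 28-day cycle (1040 mg at 65 kg)."""
        return self.weight_kg * self.ram_mg_per_kg * self.ram_infusions_per_cycle

    @property
    def pac_mg_per_cycle(self) -> float:
        return self.bsa_m2 * self.pac_mg_per_m2 * self.pac_infusions_per_cycle


@dataclass(frozen=True)
class CostInputs:
    """Unit costs (2018 USD).  Exactly one ramucirumab price may be given,
    either per 4-week cycle or per mg."""

    pac_per_30mg: float = 116.2
    admin_per_unit: float = 18.6
    lab_per_unit: float = 88.2
    bsc_per_cycle: float = 1425.1
    ct_per_unit: float = 105.9
    ae_episode_costs: Mapping[str, float] = field(
        default_factory=lambda: {
            "fatigue_appetite": 116.2,
            "abdominal_pain_diarrhoea": 44.6,
            "nausea_vomiting": 40.0,
            "neutropenia": 534.4,
            "hypertension": 16.6,
        }
    )
    ram_price_per_cycle: float | None = None
    ram_price_per_mg: float | None = None

    def __post_init__(self) -> None:
        scalars = [
            self.pac_per_30mg,
            self.admin_per_unit,
            self.lab_per_unit,
            self.bsc_per_cycle,
            self.ct_per_unit,
            *self.ae_episode_costs.values(),
        ]
        if any(v < 0 for v in scalars):
            raise ValueError("unit costs must be non-negative")
        if self.ram_price_per_cycle is not None and self.ram_price_per_mg is not None:
            raise CostingError(
                "set ram_price_per_cycle or ram_price_per_mg, not both"
            )

    def resolve_ram_price_per_cycle(self, dosing: DosingSpec) -> float:
        if self.ram_price_per_cycle is not None:
            return self.ram_price_per_cycle
        if self.ram_price_per_mg is not None:
            return self.ram_price_per_mg * dosing.ram_mg_per_cycle
        return 0.0

    def with_ram_price_per_cycle(self, price: float) -> "CostInputs":
        return replace(self, ram_price_per_cycle=price, ram_price_per_mg=None)


@dataclass(frozen=True)
class AEProfile:
    """Grade-3/4 adverse-event risks for one treatment arm."""

    risks: Mapping[str, float]
    arm: str = ""

    def __post_init__(self) -> None:
        for name, r in self.risks.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"AE risk {name!r} must be in [0, 1], got {r}")


def per_mg_to_per_cycle(price_per_mg: float, dosing: DosingSpec) -> float:
    """Convert a ramucirumab per-mg price to a per-4-week-cycle cost."""
    return price_per_mg * dosing.ram_mg_per_cycle


def per_cycle_to_per_mg(price_per_cycle: float, dosing: DosingSpec) -> float:
    return price_per_cycle / dosing.ram_mg_per_cycle


def drug_cost_per_cycle(
    dosing: DosingSpec, costs: CostInputs, arm: str
) -> dict[str, float]:
    """Per-cycle drug acquisition cost, itemised by agent.

    ``arm`` is "ram" (ramucirumab + paclitaxel) or "pla" (placebo +
    paclitaxel); the placebo arm has a zero ramucirumab component.
    """
    if arm not in ("ram", "pla"):
        raise ValueError(f"arm must be 'ram' or 'pla', got {arm!r}")
    pac = dosing.pac_mg_per_cycle * costs.pac_per_30mg / 30.0
    ram = costs.resolve_ram_price_per_cycle(dosing) if arm == "ram" else 0.0
    return {"ram": ram, "pac": pac}


def expected_ae_cost(profile: AEProfile, costs: CostInputs) -> float:
    """One-off expected adverse-event management cost per modelled patient."""
    if set(profile.risks) != set(costs.ae_episode_costs):
        raise CostingError(
            "AE risk categories do not match episode-cost categories: "
            f"{sorted(profile.risks)} vs {sorted(costs.ae_episode_costs)}"
        )
    return float(
        sum(profile.risks[k] * costs.ae_episode_costs[k] for k in profile.risks)
    )


@dataclass(frozen=True)
class CostBreakdown:
    """Itemised strategy cost; values are (undiscounted, discounted) pairs."""

    items: Mapping[str, tuple[float, float]]

    @property
    def total(self) -> float:
        return float(sum(v[1] for v in self.items.values()))

    @property
    def total_undiscounted(self) -> float:
        return float(sum(v[0] for v in self.items.values()))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(k, v[0], v[1]) for k, v in self.items.items()],
            columns=["item", "undiscounted", "discounted"],
        )


def strategy_cost(
    trace: CohortTrace,
    dosing: DosingSpec,
    costs: CostInputs,
    profile: AEProfile,
    cfg: ModelConfig,
    arm: str,
) -> CostBreakdown:
    """Total discounted cost of one strategy given its occupancy trace."""
    drug = drug_cost_per_cycle(dosing, costs, arm)
    ct_per_cycle = costs.ct_per_unit * cfg.cycle_length_days / CT_INTERVAL_DAYS
    pfs_rates = {
        "drug_ram": drug["ram"],
        "drug_pac": drug["pac"],
        "administration": costs.admin_per_unit * dosing.pac_infusions_per_cycle,
        "laboratory": costs.lab_per_unit,
        "imaging_ct": ct_per_cycle,
    }
    pfs_u = cycle_weights(trace.pfs, cfg).sum()
    pfs_d = cycle_weights(trace.pfs * trace.discount, cfg).sum()
    pd_u = cycle_weights(trace.pd, cfg).sum()
    pd_d = cycle_weights(trace.pd * trace.discount, cfg).sum()

    items: dict[str, tuple[float, float]] = {
        name: (rate * pfs_u, rate * pfs_d) for name, rate in pfs_rates.items()
    }
    items["best_supportive_care"] = (
        costs.bsc_per_cycle * pd_u,
        costs.bsc_per_cycle * pd_d,
    )
    ae = expected_ae_cost(profile, costs)
    items["adverse_events"] = (ae, ae)  # one-off at model entry, weight 1
    return CostBreakdown(items=items)


def regimen_annual_cost(
    dosing: DosingSpec,
    c1_per_mg: float,
    c2_per_30mg: float,
    n_cycles: int = 13,
) -> float:
    """Acquisition cost of the full combination for ``n_cycles`` cycles.

    (weight x 2 x 8 x C1 + bsa x 80 x 3 x C2/30) x n_cycles, ignoring
    interruptions and dose reductions; 13 cycles span 364 days.
    """
    per_cycle = (
        dosing.ram_mg_per_cycle * c1_per_mg
        + dosing.pac_mg_per_cycle * c2_per_30mg / 30.0
    )
    return per_cycle * n_cycles
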