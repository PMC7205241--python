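"""Model time grid, horizon and discounting configuration.

The cohort model advances in fixed 28-day cycles over a 5-year horizon.
Survival curves are parameterised in months, so cycle indices are converted
to months with an average-month length of 30.4375 days (365.25 / 12).
Costs and QALYs are discounted at 3% per year by continuous compounding of
whole elapsed years; life-years are undiscounted unless requested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace


@dataclass(frozen=True)
class ModelConfig:
    """Time grid and discounting settings for the cohort engine.

    Parameters
    ----------
    cycle_length_days:
        Length of one model cycle in days (28: the ramucirumab schedule).
    horizon_years:
        Simulated horizon; only whole cycles are run (5 years -> 65 cycles).
    annual_discount_rate:
        Yearly discount rate applied to costs and QALYs, in [0, 0.08].
    days_per_month:
        Conversion used to evaluate month-parameterised survival curves at
        cycle boundaries.
    half_cycle_correction:
        If True, per-cycle quantities are accumulated by the trapezoid rule
        over adjacent cycle boundaries (transitions happen mid-cycle on
        average); if False a left-endpoint sum is used.
    discount_life_years:
        Life-years are reported undiscounted by default; set True to apply
        the same discount weights as costs/QALYs.
    """

    cycle_length_days: float = 28.0
    horizon_years: float = 5.0
    annual_discount_rate: float = 0.03
    days_per_month: float = 30.4375
    days_per_year: float = 365.0
    half_cycle_correction: bool = True
    discount_life_years: bool = False

    def __post_init__(self) -> None:
        if self.cycle_length_days <= 0:
            raise ValueError("cycle_length_days must be positive")
        if self.horizon_years <= 0:
            raise ValueError("horizon_years must be positive")
        if not 0.0 <= self.annual_discount_rate <= 0.08:
            raise ValueError(
                "annual_discount_rate must lie in [0, 0.08], got "
                f"{self.annual_discount_rate}"
            )

    @property
    def n_cycles(self) -> int:
        """Number of whole cycles on the horizon (65 in the base case)."""
        return math.floor(self.horizon_years * self.days_per_year / self.cycle_length_days)

    @property
    def cycle_years(self) -> float:
        """Calendar years elapsed per cycle (28/365)."""
        return self.cycle_length_days / self.days_per_year

    def months_at(self, u) -> float:
        """Model time in months at the start of cycle ``u``."""
        import numpy as np

        return np.asarray(u, dtype=float) * self.cycle_length_days / self.days_per_month

    def years_at(self, u) -> float:
        import numpy as np

        return np.asarray(u, dtype=float) * self.cycle_length_days / self.days_per_year

    def discount_factor(self, u):
        """Discount weight (1 + r)^(-elapsed years) at cycle ``u``; 1 at u = 0."""
        import numpy as np

        u = np.asarray(u, dtype=float)
        if np.any(u < 0):
            raise ValueError("cycle index must be non-negative")
        return (1.0 + self.annual_discount_rate) ** (-self.years_at(u))

    def with_(self, **kwargs) -> "ModelConfig":
        """Functional update helper (frozen dataclass)."""
        return replace(self, **kwargs)


def discount_factor(cfg: ModelConfig, u):
    """Module-level alias for :meth:`ModelConfig.discount_factor`."""
    return cfg.discount_factor(u)
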