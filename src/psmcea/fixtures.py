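"""Baseline model inputs: fitted survival parameters and economic parameters.

These are the published inputs of the Chinese-payer evaluation of
second-line ramucirumab + paclitaxel (RAM) versus placebo + paclitaxel
(PLA) in advanced gastric / gastro-oesophageal cancer: log-logistic
survival parameters per arm and endpoint, unit costs in 2018 USD with
one-way sensitivity ranges and sampling families, grade-3/4 adverse-event
risks, utilities, and the two willingness-to-pay scenarios (mainland
China: 3x 2017 per-capita GDP; Beijing: 3x the municipal figure).
"""

from __future__ import annotations

from .cohort import UtilitySet
from .config import ModelConfig
from .costing import AEProfile, CostInputs, DosingSpec
from .survival import LogLogisticParams

# (arm, endpoint) -> (theta, kappa); time unit is months
SURVIVAL_PARAMS: dict[tuple[str, str], tuple[float, float]] = {
    ("ram", "pfs"): (-3.157, 2.058),
    ("pla", "pfs"): (-2.268, 2.042),
    ("ram", "os"): (-4.671, 2.089),
    ("pla", "os"): (-3.337, 1.681),
}

# parameter id -> (baseline, low, high, family)
ECONOMIC_PARAMS: dict[str, tuple[float, float, float, str]] = {
    "cost_pac_per_30mg": (116.2, 58.1, 174.3, "lognormal"),
    "cost_admin_per_unit": (18.6, 16.6, 23.2, "lognormal"),
    "cost_lab_per_unit": (88.2, 35.4, 184.0, "lognormal"),
    "cost_bsc_per_cycle": (1425.1, 1029.8, 2035.4, "lognormal"),
    "cost_ct_per_unit": (105.9, 53.0, 158.9, "lognormal"),
    "cost_ae_fatigue_appetite": (116.2, 104.5, 127.8, "lognormal"),
    "cost_ae_abdominal_pain_diarrhoea": (44.6, 28.7, 55.0, "lognormal"),
    "cost_ae_nausea_vomiting": (40.0, 18.0, 77.0, "lognormal"),
    "cost_ae_neutropenia": (534.4, 199.9, 869.0, "lognormal"),
    "cost_ae_hypertension": (16.6, 14.9, 18.15, "lognormal"),
    "risk_ram_fatigue_appetite": (0.15, 0.12, 0.18, "beta"),
    "risk_ram_abdominal_pain_diarrhoea": (0.098, 0.0784, 0.1176, "beta"),
    "risk_ram_nausea_vomiting": (0.043, 0.0344, 0.0516, "beta"),
    "risk_ram_neutropenia": (0.41, 0.328, 0.492, "beta"),
    "risk_ram_hypertension": (0.14, 0.112, 0.168, "beta"),
    "risk_pla_fatigue_appetite": (0.094, 0.0752, 0.1128, "beta"),
    "risk_pla_abdominal_pain_diarrhoea": (0.043, 0.0344, 0.0516, "beta"),
    "risk_pla_nausea_vomiting": (0.061, 0.0488, 0.0732, "beta"),
    "risk_pla_neutropenia": (0.19, 0.152, 0.228, "beta"),
    "risk_pla_hypertension": (0.02, 0.016, 0.024, "beta"),
    "utility_pd": (0.42, 0.28, 0.63, "beta"),
    "utility_pfs": (0.68, 0.61, 0.75, "beta"),
    "weight_kg": (65.0, 52.0, 78.0, "lognormal"),
    "bsa_m2": (1.62, 1.296, 2.43, "lognormal"),
    "discount_rate": (0.03, 0.0, 0.08, "fixed"),
}

# region -> (WTP $/QALY, base-case RAM price $/4-week cycle)
WTP_SCENARIOS: dict[str, tuple[float, float]] = {
    "mainland": (26022.0, 244.0),
    "beijing": (56263.0, 604.0),
}

# 1.5x per-capita-GDP variants of the same thresholds
WTP_LOW_VARIANTS: dict[str, float] = {"mainland": 13010.95, "beijing": 28131.65}


def survival_params(arm: str, endpoint: str) -> LogLogisticParams:
    theta, kappa = SURVIVAL_PARAMS[(arm, endpoint)]
    return LogLogisticParams(theta=theta, kappa=kappa, label=f"{arm.upper()}-{endpoint.upper()}")


def default_config() -> ModelConfig:
    return ModelConfig()


def default_dosing() -> DosingSpec:
    return DosingSpec()


def default_utilities() -> UtilitySet:
    return UtilitySet(
        u_pfs=ECONOMIC_PARAMS["utility_pfs"][0], u_pd=ECONOMIC_PARAMS["utility_pd"][0]
    )


def default_costs(ram_price_per_cycle: float | None = None) -> CostInputs:
    p = {k: v[0] for k, v in ECONOMIC_PARAMS.items()}
    return CostInputs(
        pac_per_30mg=p["cost_pac_per_30mg"],
        admin_per_unit=p["cost_admin_per_unit"],
        lab_per_unit=p["cost_lab_per_unit"],
        bsc_per_cycle=p["cost_bsc_per_cycle"],
        ct_per_unit=p["cost_ct_per_unit"],
        ae_episode_costs={
            "fatigue_appetite": p["cost_ae_fatigue_appetite"],
            "abdominal_pain_diarrhoea": p["cost_ae_abdominal_pain_diarrhoea"],
            "nausea_vomiting": p["cost_ae_nausea_vomiting"],
            "neutropenia": p["cost_ae_neutropenia"],
            "hypertension": p["cost_ae_hypertension"],
        },
        ram_price_per_cycle=ram_price_per_cycle,
    )


def default_ae_profile(arm: str) -> AEProfile:
    risks = {
        k.removeprefix(f"risk_{arm}_"): v[0]
        for k, v in ECONOMIC_PARAMS.items()
        if k.startswith(f"risk_{arm}_")
    }
    if not risks:
        raise KeyError(f"unknown arm {arm!r}")
    return AEProfile(risks=risks, arm=arm)
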