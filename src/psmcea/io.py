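"""Readers and writers for the package's delimited-text and YAML formats.

Everything is plain text: survival-curve points and tabular outputs are
tab/comma-delimited with headers, parameter fixtures and run manifests are
YAML with explicit units in key names.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortTrace
from .config import ModelConfig
from .survival import LogLogisticParams, SurvivalPoints


# --------------------------------------------------------------------------- #
# survival points (two-column delimited text)
# --------------------------------------------------------------------------- #


def write_survival_points(path, points: SurvivalPoints) -> None:
    points.to_frame().to_csv(path, sep="\t", index=False)


def read_survival_points(path) -> SurvivalPoints:
    df = pd.read_csv(path, sep="\t")
    missing = {"time_months", "survival"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return SurvivalPoints(
        times=df["time_months"].to_numpy(dtype=float),
        survival=df["survival"].to_numpy(dtype=float),
    )


# --------------------------------------------------------------------------- #
# parameter fixtures (YAML)
# --------------------------------------------------------------------------- #


def write_survival_params(path, params: dict[tuple[str, str], LogLogisticParams]) -> None:
    rows = [
        {"arm": arm, "endpoint": endpoint, "theta": p.theta, "kappa": p.kappa}
        for (arm, endpoint), p in params.items()
    ]
    Path(path).write_text(yaml.safe_dump({"loglogistic_params_months": rows}, sort_keys=False))


def read_survival_params(path) -> dict[tuple[str, str], LogLogisticParams]:
    data = yaml.safe_load(Path(path).read_text())
    out = {}
    for row in data["loglogistic_params_months"]:
        key = (row["arm"], row["endpoint"])
        out[key] = LogLogisticParams(
            theta=float(row["theta"]),
            kappa=float(row["kappa"]),
            label=f"{row['arm'].upper()}-{row['endpoint'].upper()}",
        )
    return out


def write_economic_params(
    path, params: dict[str, tuple[float, float, float, str]]
) -> None:
    rows = {
        name: {
            "baseline": baseline,
            "low": low,
            "high": high,
            "distribution": family,
        }
        for name, (baseline, low, high, family) in params.items()
    }
    Path(path).write_text(
        yaml.safe_dump({"currency": "2018 USD", "parameters": rows}, sort_keys=False)
    )


def read_economic_params(path) -> dict[str, tuple[float, float, float, str]]:
    data = yaml.safe_load(Path(path).read_text())
    return {
        name: (
            float(row["baseline"]),
            float(row["low"]),
            float(row["high"]),
            str(row["distribution"]),
        )
        for name, row in data["parameters"].items()
    }


def write_model_config(path, cfg: ModelConfig) -> None:
    Path(path).write_text(yaml.safe_dump({"model_config": asdict(cfg)}, sort_keys=False))


def read_model_config(path) -> ModelConfig:
    data = yaml.safe_load(Path(path).read_text())
    return ModelConfig(**data["model_config"])


# --------------------------------------------------------------------------- #
# tabular outputs
# --------------------------------------------------------------------------- #


def write_trace(path, trace: CohortTrace) -> None:
    trace.to_frame().to_csv(path, index=False)


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def comparison_table(rows: list[dict]) -> pd.DataFrame:
    """Base-case results in the shape of the published summary table."""
    cols = [
        "scenario",
        "wtp_usd_per_qaly",
        "ram_price_per_cycle_usd",
        "total_cost_ram_usd",
        "total_cost_pla_usd",
        "ly_ram",
        "ly_pla",
        "qaly_ram",
        "qaly_pla",
        "delta_cost_usd",
        "delta_ly",
        "delta_qaly",
        "icer_usd_per_ly",
        "icer_usd_per_qaly",
        "nmb_usd",
    ]
    return pd.DataFrame(rows, columns=cols)


# --------------------------------------------------------------------------- #
# run manifest
# --------------------------------------------------------------------------- #


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record written next to every command's outputs."""

    command: str
    config: dict
    seeds: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # path -> sha256
    outputs: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)
    package_version: str = ""

    def add_input(self, path) -> None:
        self.inputs[str(path)] = _sha256(path)

    def add_output(self, path) -> None:
        self.outputs[str(path)] = _sha256(path)

    def write(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def read_manifest(path) -> RunManifest:
    data = yaml.safe_load(Path(path).read_text())
    return RunManifest(**data)
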