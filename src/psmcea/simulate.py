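"""Synthetic survival data with the structure the fitting stage assumes.

Event times are drawn from a log-logistic distribution by inverse-CDF
(t = median * (1/U - 1)^(1/kappa)), right-censored by an administrative
cutoff and/or an independent exponential censoring process.  A product-
limit (Kaplan-Meier) estimate turns a sample into survival-curve points,
and truncated Gaussian jitter with isotonic repair emulates the error of
digitizing a published curve.  None of this reproduces trial covariates
or regional strata; it exercises exactly the statistical pathway
(curve -> pseudo-IPD -> parametric fit) the economic model rests on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .survival import IPDSample, LogLogisticParams, SurvivalPoints, median_survival


@dataclass(frozen=True)
class SimulationSpec:
    """Ground truth and censoring scheme for one simulated endpoint.

    ``censor_rate_per_month`` is the hazard of an independent exponential
    censoring process (0 disables it); ``cutoff_months`` is administrative
    censoring at end of follow-up (inf disables it).  Defaults emulate a
    trial-like 30-month follow-up with a light random-censoring hazard.
    """

    params: LogLogisticParams
    n: int
    cutoff_months: float = 30.0
    censor_rate_per_month: float = 0.01
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("sample size must be >= 1")
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")
        if self.cutoff_months <= 0:
            raise ValueError("cutoff must be positive")
        if self.censor_rate_per_month < 0:
            raise ValueError("censoring rate must be non-negative")


def loglogistic_rvs(
    params: LogLogisticParams, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Inverse-CDF draws: t = exp(-theta/kappa) (1/U - 1)^(1/kappa)."""
    u = rng.uniform(size=n)
    return median_survival(params) * (1.0 / u - 1.0) ** (1.0 / params.kappa)


def simulate_ipd(spec: SimulationSpec) -> IPDSample:
    """Draw a right-censored pseudo-IPD sample; deterministic under seed."""
    rng = np.random.default_rng(spec.seed)
    t_event = loglogistic_rvs(spec.params, spec.n, rng)
    t_censor = np.full(spec.n, spec.cutoff_months)
    if spec.censor_rate_per_month > 0:
        t_censor = np.minimum(
            t_censor, rng.exponential(1.0 / spec.censor_rate_per_month, size=spec.n)
        )
    times = np.minimum(t_event, t_censor)
    events = (t_event <= t_censor).astype(int)
    # guard against zero times from floating underflow at U ~ 1
    times = np.maximum(times, 1e-12)
    return IPDSample(times=times, events=events)


def km_estimate(ipd: IPDSample) -> SurvivalPoints:
    """Product-limit survival estimate as a right-continuous step function."""
    if len(ipd) == 0:
        raise ValueError("empty sample")
    if ipd.n_events == 0:
        raise ValueError("Kaplan-Meier estimate needs at least one event")
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter()
    km.fit(ipd.times, event_observed=ipd.events)
    sf = km.survival_function_
    t = sf.index.to_numpy(dtype=float)
    s = sf.iloc[:, 0].to_numpy(dtype=float)
    pos = t > 0
    return SurvivalPoints(times=t[pos], survival=s[pos])


def add_digitization_noise(
    points: SurvivalPoints, jitter: float, seed: int = 0
) -> SurvivalPoints:
    """Perturb survival values like a hand-digitized curve.

    Gaussian noise truncated at +-3 sigma is added on the survival scale,
    the result is clipped to [0, 1] and monotonicity is restored by an
    isotonic (non-increasing least-squares) repair, keeping the point
    count unchanged.  ``jitter = 0`` returns the input untouched.
    """
    if jitter < 0:
        raise ValueError("jitter must be non-negative")
    if jitter == 0:
        return points
    rng = np.random.default_rng(seed)
    noise = np.clip(rng.normal(0.0, jitter, size=len(points)), -3 * jitter, 3 * jitter)
    noisy = np.clip(points.survival + noise, 0.0, 1.0)
    from sklearn.isotonic import IsotonicRegression

    iso = IsotonicRegression(increasing=False, y_min=0.0, y_max=1.0)
    repaired = iso.fit_transform(points.times, noisy)
    # enforce strict non-increase against float fuzz
    repaired = np.minimum.accumulate(repaired)
    return SurvivalPoints(times=points.times.copy(), survival=repaired)


def make_fixture_bundle(outdir) -> dict[str, str]:
    """Write the baseline input files (survival parameters, economic
    parameters, model configuration) to ``outdir``; returns name -> path."""
    from pathlib import Path

    from . import fixtures, io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "survival_params": outdir / "survival_params.yaml",
        "economic_params": outdir / "economic_params.yaml",
        "model_config": outdir / "model_config.yaml",
    }
    io.write_survival_params(
        paths["survival_params"],
        {key: fixtures.survival_params(*key) for key in fixtures.SURVIVAL_PARAMS},
    )
    io.write_economic_params(paths["economic_params"], fixtures.ECONOMIC_PARAMS)
    io.write_model_config(paths["model_config"], fixtures.default_config())
    return {k: str(v) for k, v in paths.items()}
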