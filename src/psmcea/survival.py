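"""Log-logistic survival curves, per-cycle transition probabilities and fitting.

The two-parameter log-logistic survival function used throughout is

    S(t) = 1 / (1 + exp(theta) * t**kappa),      t >= 0, kappa > 0,

with median survival exp(-theta/kappa).  ``theta`` is a log-scale parameter
(more negative -> longer survival), ``kappa`` a shape parameter.  Per-cycle
probabilities condition on being event-free at the start of a cycle:

    stay(u)  = S(t_{u+1}) / S(t_u)
    event(u) = 1 - stay(u)

where t_u is the cycle-start time in months.  Note the conditional form
(1 + e^theta u^kappa) / (1 + e^theta (u+1)^kappa) is the probability of
REMAINING event-free over the cycle, even though source material sometimes
labels it a progression probability; the complement is the transition
probability.

Fitting supports maximum likelihood on right-censored pseudo-individual
patient data (via lifelines) and least squares on digitized survival-curve
points (via scipy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit


# --------------------------------------------------------------------------- #
# domain types
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class LogLogisticParams:
    """Parameters (theta, kappa) of one arm/endpoint survival curve."""

    theta: float
    kappa: float
    label: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.theta):
            raise ValueError("theta must be finite")
        if not (math.isfinite(self.kappa) and self.kappa > 0):
            raise ValueError(f"kappa must be positive, got {self.kappa}")

    # convenience method forms of the module-level operations
    def survival(self, t):
        return survival_probability(self, t)

    def median(self) -> float:
        return median_survival(self)


@dataclass(frozen=True)
class SurvivalPoints:
    """A digitized survival step function: (time in months, survival) pairs."""

    times: np.ndarray
    survival: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "survival", s)
        if t.ndim != 1 or t.shape != s.shape:
            raise ValueError("times and survival must be 1-d arrays of equal length")
        if len(t) and t[0] < 0:
            raise ValueError("times must be non-negative")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("survival must be non-increasing")
        if len(s) and (s[0] > 1.0 + 1e-12 or s[-1] < -1e-12):
            raise ValueError("survival values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.times, "survival": self.survival})


@dataclass(frozen=True)
class IPDSample:
    """Pseudo-individual-patient data: positive times with event/censor flags."""

    times: np.ndarray
    events: np.ndarray  # 1 = event observed, 0 = right-censored

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.events, dtype=int)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "events", e)
        if t.shape != e.shape or t.ndim != 1:
            raise ValueError("times and events must be 1-d arrays of equal length")
        if np.any(~np.isfinite(t)) or np.any(t <= 0):
            raise ValueError("all times must be finite and positive")
        if not np.isin(e, (0, 1)).all():
            raise ValueError("event flags must be 0 or 1")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.times, "event": self.events})


@dataclass
class FitResult:
    """Outcome of a log-logistic fit, with standard errors when available."""

    params: LogLogisticParams
    se_theta: float | None
    se_kappa: float | None
    converged: bool
    method: str
    n_obs: int
    n_events: int
    message: str = ""
    loglik: float | None = None
    extra: dict = field(default_factory=dict)


class FitError(RuntimeError):
    """Raised when a survival fit cannot be performed or did not converge."""


# --------------------------------------------------------------------------- #
# survival function and transition probabilities
# --------------------------------------------------------------------------- #


def _log_odds(params: LogLogisticParams, t: np.ndarray) -> np.ndarray:
    """theta + kappa*log(t), the log of the cumulative odds of the event."""
    out = np.full_like(t, -np.inf, dtype=float)
    pos = t > 0
    with np.errstate(divide="ignore"):
        out[pos] = params.theta + params.kappa * np.log(t[pos])
    return out


def survival_probability(params: LogLogisticParams, t):
    """S(t) = 1 / (1 + exp(theta) t^kappa); S(0) = 1 exactly.

    ``t`` is in months and may be a scalar or array.  Negative times raise.
    The evaluation runs in log space (via the logistic sigmoid), so large
    t^kappa cannot overflow.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    s = expit(-_log_odds(params, np.atleast_1d(t_arr)))
    s = s.reshape(t_arr.shape)
    return float(s) if np.isscalar(t) or t_arr.ndim == 0 else s


def stay_probability(params: LogLogisticParams, u, cfg) -> float:
    """Probability of remaining event-free across cycle ``u`` (conditional).

    Equals S(t_{u+1}) / S(t_u) with t_u = cfg.months_at(u); computed as
    exp(log1pexp(a_u) - log1pexp(a_{u+1})) for numerical stability.
    """
    u_arr = np.asarray(u, dtype=float)
    if np.any(u_arr < 0):
        raise ValueError("cycle index must be non-negative")
    a0 = _log_odds(params, np.atleast_1d(np.asarray(cfg.months_at(u_arr), dtype=float)))
    a1 = _log_odds(params, np.atleast_1d(np.asarray(cfg.months_at(u_arr + 1), dtype=float)))
    # log(1 + e^a) with the a = -inf (t = 0) case mapping to 0
    l0 = np.logaddexp(0.0, a0)
    l1 = np.logaddexp(0.0, a1)
    out = np.exp(l0 - l1).reshape(u_arr.shape)
    return float(out) if np.isscalar(u) or u_arr.ndim == 0 else out


def event_probability(params: LogLogisticParams, u, cfg):
    """Probability of the event during cycle ``u``; complement of stay."""
    return 1.0 - stay_probability(params, u, cfg)


def median_survival(params: LogLogisticParams) -> float:
    """Closed-form median exp(-theta/kappa), in months."""
    return math.exp(-params.theta / params.kappa)


# --------------------------------------------------------------------------- #
# fitting
# --------------------------------------------------------------------------- #


def _fit_mle(data: IPDSample, label: str) -> FitResult:
    # lifelines parameterises S(t) = 1/(1 + (t/alpha)^beta):
    # beta = kappa, alpha = exp(-theta/kappa)
    from lifelines import LogLogisticFitter
    from lifelines.exceptions import ConvergenceError

    try:
        fitter = LogLogisticFitter()
        fitter.fit(data.times, event_observed=data.events)
    except (ConvergenceError, ValueError) as exc:  # pragma: no cover - rare
        raise FitError(f"log-logistic MLE did not converge: {exc}") from exc

    alpha = float(fitter.alpha_)
    beta = float(fitter.beta_)
    kappa = beta
    theta = -kappa * math.log(alpha)
    # delta method for (theta, kappa) = g(alpha, beta):
    #   dtheta/dalpha = -beta/alpha, dtheta/dbeta = -log(alpha), dkappa/dbeta = 1
    cov = fitter.variance_matrix_.loc[["alpha_", "beta_"], ["alpha_", "beta_"]].to_numpy()
    jac = np.array([[-beta / alpha, -math.log(alpha)], [0.0, 1.0]])
    cov_tk = jac @ cov @ jac.T
    se_theta = math.sqrt(max(cov_tk[0, 0], 0.0))
    se_kappa = math.sqrt(max(cov_tk[1, 1], 0.0))
    return FitResult(
        params=LogLogisticParams(theta=theta, kappa=kappa, label=label),
        se_theta=se_theta,
        se_kappa=se_kappa,
        converged=True,
        method="mle",
        n_obs=len(data),
        n_events=data.n_events,
        loglik=float(fitter.log_likelihood_),
    )


def _fit_least_squares(points: SurvivalPoints, label: str) -> FitResult:
    mask = points.times > 0
    t = points.times[mask]
    s = np.clip(points.survival[mask], 0.0, 1.0)
    if len(t) < 5:
        raise FitError("least-squares fitting needs at least 5 positive-time points")

    def residuals(x):
        theta, log_kappa = x
        p = LogLogisticParams(theta=theta, kappa=math.exp(log_kappa))
        return survival_probability(p, t) - s

    # moment-style start: logit-linear regression of log odds on log t
    s_in = np.clip(s, 1e-6, 1 - 1e-6)
    y = np.log((1 - s_in) / s_in)
    slope, intercept = np.polyfit(np.log(t), y, 1)
    x0 = np.array([intercept, math.log(max(slope, 1e-3))])
    sol = optimize.least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14)
    if not sol.success:
        raise FitError(f"least-squares fit failed: {sol.message}")
    theta, log_kappa = sol.x
    return FitResult(
        params=LogLogisticParams(theta=float(theta), kappa=float(math.exp(log_kappa)), label=label),
        se_theta=None,
        se_kappa=None,
        converged=True,
        method="least-squares",
        n_obs=len(t),
        n_events=len(t),
        message=sol.message,
        extra={"cost": float(sol.cost)},
    )


def fit_loglogistic(
    data: IPDSample | SurvivalPoints,
    method: Literal["mle", "least-squares"] = "mle",
    label: str = "",
) -> FitResult:
    """Fit log-logistic parameters to censored IPD (MLE) or curve points (LS).

    Parameters
    ----------
    data:
        :class:`IPDSample` for ``method="mle"`` (needs >= 10 observations and
        at least 2 events) or :class:`SurvivalPoints` for
        ``method="least-squares"`` (needs >= 5 positive-time points).
    method:
        ``"mle"`` maximises the right-censored log-logistic likelihood and
        reports delta-method standard errors on (theta, kappa);
        ``"least-squares"`` minimises squared deviation from the points.

    Raises
    ------
    FitError
        On degenerate input (too few observations/events, all censored) or
        non-convergence.
    """
    if method == "mle":
        if not isinstance(data, IPDSample):
            raise TypeError("MLE fitting requires an IPDSample")
        if len(data) < 10:
            raise FitError(f"MLE fitting needs >= 10 observations, got {len(data)}")
        if data.n_events < 2:
            raise FitError(
                f"MLE fitting needs at least 2 observed events, got {data.n_events}"
            )
        return _fit_mle(data, label)
    if method == "least-squares":
        if isinstance(data, IPDSample):
            raise TypeError("least-squares fitting requires SurvivalPoints")
        return _fit_least_squares(data, label)
    raise ValueError(f"unknown fitting method {method!r}")
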