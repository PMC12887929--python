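"""Data-generating process for interrupted time-series (ITS) power simulation.

An ITS study observes an aggregated outcome at regular timepoints before and
after an intervention.  The simulator builds each synthetic series additively
from four components:

* stationary ARMA(p, q) errors driven by Gaussian innovations,
* an intervention regressor (step, pulse or change-in-trend coding),
* optionally a time-varying covariate, generated as an AR(1) process with
  lag-one correlation 0.5 whose level may shift after the intervention,
* optionally a baseline trend, either deterministic (linear in time) or
  stochastic (a scaled random walk).

Timepoints are indexed 1..t; the intervention takes effect at timepoint k+1.
All coefficients are on the outcome scale, or on the log-outcome scale when
``log_scale`` is set (the simulated ``y`` is then the log outcome and a
coefficient ``b`` corresponds to a multiplicative effect ``exp(b)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

__all__ = [
    "ErrorModelSpec",
    "InterventionSpec",
    "CovariateSpec",
    "TrendSpec",
    "ScenarioConfig",
    "SimulatedSeries",
    "ValidationError",
    "validate_error_model",
    "simulate_arma_errors",
    "build_intervention_regressor",
    "simulate_covariate",
    "build_baseline_trend",
    "assemble_series",
]

#: lag-one autocorrelation of the simulated covariate process
COVARIATE_RHO = 0.5


class ValidationError(ValueError):
    """A scenario component violates its constraints."""


def _as_float_vector(x: Optional[Sequence[float]]) -> tuple[float, ...]:
    if x is None:
        return ()
    return tuple(float(v) for v in np.atleast_1d(x))


@dataclass(frozen=True)
class ErrorModelSpec:
    """ARIMA error model for the residual process.

    ``ar_coefs`` / ``ma_coefs`` parameterise a stationary, invertible
    ARMA(p, q) process; ``noise_sd`` is the standard deviation of the
    Gaussian innovations.  ``d`` is the differencing order applied by the
    *analysis* model only — simulated errors are always generated at d=0.
    """

    ar_coefs: tuple[float, ...] = ()
    ma_coefs: tuple[float, ...] = ()
    d: int = 0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "ar_coefs", _as_float_vector(self.ar_coefs))
        object.__setattr__(self, "ma_coefs", _as_float_vector(self.ma_coefs))

    @property
    def p(self) -> int:
        return len(self.ar_coefs)

    @property
    def q(self) -> int:
        return len(self.ma_coefs)

    @property
    def order(self) -> tuple[int, int, int]:
        return (self.p, self.d, self.q)


@dataclass(frozen=True)
class InterventionSpec:
    """Intervention effect type and magnitude.

    kind
        ``step``: immediate, sustained level change from timepoint k+1 on.
        ``pulse``: temporary level change lasting ``pulse_duration``
        timepoints, then reverting to baseline.
        ``trend_change``: the per-timepoint slope changes by ``effect_size``
        from timepoint k+1 on.
    """

    kind: Literal["step", "pulse", "trend_change"] = "step"
    effect_size: float = 0.0
    pulse_duration: int = 1


@dataclass(frozen=True)
class CovariateSpec:
    """Time-varying covariate (confounder) settings.

    The covariate is an AR(1) process with lag-one correlation 0.5,
    marginal mean ``mean`` and marginal standard deviation ``sd``;
    ``shift_after_k`` is added to its level from timepoint k+1 onward,
    which makes it a confounder of the intervention.  ``include_in_dgp``
    adds ``beta`` times the covariate to the outcome; ``include_in_model``
    controls whether the analysis model adjusts for it (setting it False
    while the covariate is in the DGP is the omitted-variable scenario).
    """

    beta: float = 0.0
    mean: float = 0.0
    sd: float = 0.0
    shift_after_k: float = 0.0
    include_in_dgp: bool = False
    include_in_model: bool = False


@dataclass(frozen=True)
class TrendSpec:
    """Baseline (pre-intervention) trend settings.

    ``deterministic``: linear trend with slope ``magnitude`` per timepoint.
    ``stochastic``: ``magnitude`` scales a random walk whose increments have
    standard deviation ``stochastic_innov_sd``.

    ``model_method`` says how the analysis model accounts for the trend:
    ``none`` (ignore it), ``xreg`` (linear time regressor), or ``diff``
    (first-difference the outcome, forcing d=1 in the fitted model).
    """

    kind: Literal["deterministic", "stochastic"] = "deterministic"
    magnitude: float = 0.0
    stochastic_innov_sd: float = 0.0
    include_in_dgp: bool = False
    model_method: Literal["none", "xreg", "diff"] = "xreg"


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete description of one DGP / analysis-model pairing."""

    t: int
    k: int
    b0: float = 0.0
    period: int = 1
    intervention: InterventionSpec = field(default_factory=InterventionSpec)
    covariate: CovariateSpec = field(default_factory=CovariateSpec)
    trend: TrendSpec = field(default_factory=TrendSpec)
    error_model: ErrorModelSpec = field(default_factory=ErrorModelSpec)
    log_scale: bool = False
    alpha: float = 0.05
    n_sims: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t < 3:
            raise ValidationError(f"t must be at least 3, got {self.t}")
        if not (1 <= self.k <= self.t - 2):
            raise ValidationError(
                f"k must satisfy 1 <= k <= t-2 (k={self.k}, t={self.t})"
            )
        if self.intervention.kind == "pulse":
            if self.intervention.pulse_duration < 1:
                raise ValidationError("pulse_duration must be >= 1")
            if self.k + self.intervention.pulse_duration > self.t:
                raise ValidationError(
                    "pulse must end within the series: "
                    f"k + pulse_duration = {self.k + self.intervention.pulse_duration} > t = {self.t}"
                )
        if not (0 < self.alpha < 1):
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_sims < 1:
            raise ValidationError("n_sims must be positive")
        if self.covariate.include_in_model and not self.covariate.include_in_dgp:
            raise ValidationError(
                "covariate cannot be modelled (include_in_model=True) "
                "unless it is generated (include_in_dgp=True)"
            )
        if self.covariate.sd < 0:
            raise ValidationError("covariate sd must be non-negative")
        validate_error_model(self.error_model)

    def with_effect(self, effect_size: float) -> "ScenarioConfig":
        """Copy of this scenario with a different intervention effect size."""
        return replace(self, intervention=replace(self.intervention, effect_size=effect_size))


@dataclass(frozen=True)
class SimulatedSeries:
    """One realised outcome series together with its building blocks.

    When the fitted model applies no differencing, the components satisfy
    ``y = b0 + b1 * intervention_regressor + beta * covariate + trend + errors``
    exactly by construction.
    """

    y: np.ndarray
    intervention_regressor: np.ndarray
    covariate_values: Optional[np.ndarray]
    trend_values: Optional[np.ndarray]
    errors: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Tidy representation: one row per timepoint."""
        t = len(self.y)
        data = {
            "time": np.arange(1, t + 1),
            "y": self.y,
            "intervention": self.intervention_regressor,
        }
        if self.covariate_values is not None:
            data["covariate"] = self.covariate_values
        if self.trend_values is not None:
            data["trend"] = self.trend_values
        data["error"] = self.errors
        return pd.DataFrame(data)


def _check_roots(coefs: Sequence[float], sign: float, name: str, condition: str) -> None:
    """Require all roots of 1 + sign*c1*z + ... + sign*cp*z^p outside the unit circle."""
    for c in coefs:
        if not -1.0 < c < 1.0:
            raise ValidationError(
                f"{name} coefficient {c} outside (-1, 1); the process is not {condition}"
            )
    if len(coefs) <= 1:
        return  # box constraint is equivalent to the root condition at order 1
    poly = np.r_[1.0, sign * np.asarray(coefs, dtype=float)]
    roots = np.roots(poly[::-1])  # np.roots wants highest degree first
    moduli = np.abs(roots)
    if np.any(moduli <= 1.0 + 1e-10):
        raise ValidationError(
            f"{name} polynomial has root(s) on or inside the unit circle "
            f"(moduli {np.sort(moduli).round(4).tolist()}); the process is not {condition}"
        )


def validate_error_model(spec: ErrorModelSpec) -> ErrorModelSpec:
    """Check stationarity of the AR part and invertibility of the MA part.

    For orders above one the box constraint on the coefficients is not
    sufficient, so the characteristic roots are checked explicitly.
    Returns ``spec`` unchanged on success.
    """
    if spec.noise_sd <= 0:
        raise ValidationError(f"noise_sd must be positive, got {spec.noise_sd}")
    if spec.d not in (0, 1):
        raise ValidationError(f"differencing order d must be 0 or 1, got {spec.d}")
    _check_roots(spec.ar_coefs, sign=-1.0, name="AR", condition="stationary")
    _check_roots(spec.ma_coefs, sign=+1.0, name="MA", condition="invertible")
    return spec


def _arma_burn_in(p: int, q: int) -> int:
    return max(200, 10 * (p + q + 1))


def simulate_arma_errors(
    spec: ErrorModelSpec, t: int, rng: np.random.Generator
) -> np.ndarray:
    """Simulate a length-``t`` draw from the stationary ARMA(p, q) process.

    A burn-in segment is generated first and discarded so the returned
    segment is (to numerical accuracy) a draw from the stationary
    distribution regardless of initial conditions.
    """
    validate_error_model(spec)
    if t < 1:
        raise ValidationError(f"t must be >= 1, got {t}")
    burn = _arma_burn_in(spec.p, spec.q)
    innov = rng.normal(0.0, spec.noise_sd, size=t + burn)
    # ARMA recursion as a linear filter: a(L) e = b(L) eps
    b = np.r_[1.0, spec.ma_coefs]
    a = np.r_[1.0, -np.asarray(spec.ar_coefs, dtype=float)]
    errors = lfilter(b, a, innov)
    return errors[burn:]


def build_intervention_regressor(
    kind: str, t: int, k: int, pulse_duration: int = 1
) -> np.ndarray:
    """Intervention coding over timepoints 1..t; the effect starts at k+1.

    step         0,...,0,1,1,...,1
    pulse        0,...,0,1 (for ``pulse_duration`` points),0,...,0
    trend_change 0,...,0,1,2,3,...  (slope-change coding: the coefficient is
                 the change in per-timepoint slope after the intervention)
    """
    x = np.zeros(t)
    if kind == "step":
        x[k:] = 1.0
    elif kind == "pulse":
        x[k : k + pulse_duration] = 1.0
    elif kind == "trend_change":
        x[k:] = np.arange(1, t - k + 1)
    else:
        raise ValidationError(f"unknown intervention kind: {kind!r}")
    return x


def simulate_covariate(
    spec: CovariateSpec, t: int, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Simulate the AR(1) covariate with its post-intervention level shift.

    ``spec.sd`` is the *marginal* standard deviation of the process, so the
    innovation SD is ``sd * sqrt(1 - rho**2)`` with rho = 0.5.  A burn-in is
    discarded, then ``mean`` is added everywhere and ``shift_after_k`` from
    timepoint k+1 onward.
    """
    rho = COVARIATE_RHO
    innov_sd = spec.sd * np.sqrt(1.0 - rho**2)
    burn = 200
    innov = rng.normal(0.0, innov_sd, size=t + burn)
    x = lfilter([1.0], [1.0, -rho], innov)[burn:]
    x = x + spec.mean
    x[k:] += spec.shift_after_k
    return x


def build_baseline_trend(
    spec: TrendSpec, t: int, rng: np.random.Generator
) -> np.ndarray:
    """Baseline trend component over timepoints 1..t.

    Deterministic: ``magnitude * (0, 1, ..., t-1)`` so that the first
    timepoint carries no trend contribution and the intercept is the
    level at timepoint 1.  Stochastic: ``magnitude`` times the cumulative
    sum of Gaussian innovations with SD ``stochastic_innov_sd`` (a scaled
    random walk starting at its first increment).
    """
    if spec.kind == "deterministic":
        return spec.magnitude * np.arange(t, dtype=float)
    if spec.kind == "stochastic":
        if spec.stochastic_innov_sd < 0:
            raise ValidationError("stochastic_innov_sd must be non-negative")
        increments = rng.normal(0.0, spec.stochastic_innov_sd, size=t)
        return spec.magnitude * np.cumsum(increments)
    raise ValidationError(f"unknown trend kind: {spec.kind!r}")


def assemble_series(config: ScenarioConfig, rng: np.random.Generator) -> SimulatedSeries:
    """Assemble one outcome series from all configured components.

    The outcome is the exact element-wise sum of intercept, intervention
    effect, covariate effect, trend and ARMA errors.  With ``log_scale``
    the same arithmetic applies with every coefficient read on the log
    scale, and ``y`` is the log outcome.
    """
    t, k = config.t, config.k
    errors = simulate_arma_errors(config.error_model, t, rng)
    xi = build_intervention_regressor(
        config.intervention.kind, t, k, config.intervention.pulse_duration
    )
    y = config.b0 + config.intervention.effect_size * xi + errors

    covariate = None
    if config.covariate.include_in_dgp:
        covariate = simulate_covariate(config.covariate, t, k, rng)
        y = y + config.covariate.beta * covariate

    trend = None
    if config.trend.include_in_dgp:
        trend = build_baseline_trend(config.trend, t, rng)
        y = y + trend

    return SimulatedSeries(
        y=y,
        intervention_regressor=xi,
        covariate_values=covariate,
        trend_values=trend,
        errors=errors,
    )
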