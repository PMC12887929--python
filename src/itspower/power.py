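"""Monte Carlo power estimation and minimal-detectable-effect search.

Power is estimated as the proportion of simulated replicates in which the
intervention coefficient's two-sided p-value falls below alpha.  Each
replicate draws a fresh series (fresh errors, covariate and stochastic
trend) from the configured data-generating process, fits the analysis
model and applies the test.  Replicate random streams are spawned from the
master seed so results do not depend on execution order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .dgp import ScenarioConfig, assemble_series
from .inference import fit_scenario

__all__ = [
    "PowerEstimate",
    "PowerCurve",
    "MDEResult",
    "SimulationError",
    "estimate_power",
    "power_curve",
    "minimal_detectable_effect",
    "derive_seed",
]

#: hard failure threshold: fraction of non-converged replicates
MAX_FAILURE_FRACTION = 0.2


class SimulationError(RuntimeError):
    """The scenario is pathological (too many failed replicates, no bracket...)."""


@dataclass(frozen=True)
class PowerEstimate:
    """Rejection proportion with its binomial Monte Carlo standard error."""

    power: float
    n_effective: int
    n_requested: int
    n_failed: int
    alpha: float
    seed: int

    @property
    def mc_se(self) -> float:
        """Binomial standard error sqrt(p (1 - p) / n_effective)."""
        if self.n_effective == 0:
            return float("nan")
        return math.sqrt(self.power * (1.0 - self.power) / self.n_effective)


@dataclass(frozen=True)
class PowerCurve:
    """Power evaluated over a strictly increasing grid of effect sizes."""

    effect_grid: tuple[float, ...]
    powers: tuple[PowerEstimate, ...]

    def __post_init__(self) -> None:
        if len(self.effect_grid) != len(self.powers):
            raise ValueError("effect grid and power estimates differ in length")
        if np.any(np.diff(self.effect_grid) <= 0):
            raise ValueError("effect grid must be strictly increasing")


@dataclass(frozen=True)
class MDEResult:
    """Smallest effect magnitude reaching the target power."""

    effect: float
    achieved_power: PowerEstimate
    target_power: float
    tolerance: float
    iterations: int


def derive_seed(master_seed: int, *key: int) -> int:
    """Deterministic sub-seed (< 2**31) from a master seed and an index key."""
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, *[int(v) for v in key]])
    return int(ss.generate_state(1)[0] % (2**31))


def estimate_power(config: ScenarioConfig) -> PowerEstimate:
    """Estimate power for one scenario by Monte Carlo simulation.

    Runs ``config.n_sims`` independent replicates of simulate -> fit -> test.
    Non-converged fits are excluded from the denominator and counted in
    ``n_failed``; the run aborts if more than 20% of replicates fail, since
    power estimated from the survivors would not be trustworthy.
    """
    master = np.random.SeedSequence(config.seed)
    streams = master.spawn(config.n_sims)

    rejections = 0
    n_failed = 0
    for stream in streams:
        rng = np.random.default_rng(stream)
        series = assemble_series(config, rng)
        fit = fit_scenario(config, series)
        if not fit.converged:
            n_failed += 1
            continue
        if fit.intervention_pvalue < config.alpha:
            rejections += 1

    n_effective = config.n_sims - n_failed
    if n_failed / config.n_sims > MAX_FAILURE_FRACTION:
        raise SimulationError(
            f"{n_failed}/{config.n_sims} replicates failed to converge; "
            "the scenario is pathological (check series length, orders and "
            "coefficient values near the stationarity boundary)"
        )
    return PowerEstimate(
        power=rejections / n_effective if n_effective else float("nan"),
        n_effective=n_effective,
        n_requested=config.n_sims,
        n_failed=n_failed,
        alpha=config.alpha,
        seed=config.seed,
    )


def power_curve(config: ScenarioConfig, effect_grid: Sequence[float]) -> PowerCurve:
    """Estimate power at each effect size in a strictly increasing grid.

    Each grid point uses an independent sub-seed derived from the master
    seed, so the curve does not depend on evaluation order.
    """
    grid = tuple(float(e) for e in effect_grid)
    if not grid:
        raise ValueError("effect grid must be non-empty")
    estimates = []
    for i, effect in enumerate(grid):
        point = replace(config.with_effect(effect), seed=derive_seed(config.seed, i))
        estimates.append(estimate_power(point))
    return PowerCurve(effect_grid=grid, powers=tuple(estimates))


def minimal_detectable_effect(
    config: ScenarioConfig,
    target_power: float = 0.80,
    effect_tol: float = 0.05,
    power_tol: float = 0.01,
    initial_effect: float | None = None,
    max_doublings: int = 12,
) -> MDEResult:
    """Invert the power function: smallest |effect| with power ~ target.

    Searches on the effect magnitude assuming power is non-decreasing in
    |effect|.  The bracket ``[0, hi]`` is expanded by doubling until
    ``power(hi) >= target_power``, then bisected until either the bracket
    width falls below ``effect_tol`` (effect units) or an evaluation lands
    within ``power_tol`` of the target (``power_tol`` defaults below one
    binomial standard error at n=1000, so the bracket-width criterion, not
    sampling noise, normally ends the search).  All evaluations reuse the same
    master seed (common random numbers), which makes the estimated power
    curve monotone in the effect under the shared noise draws and keeps the
    bisection stable.  The sign of the returned effect follows the sign of
    the configured effect size.
    """
    if not (config.alpha < target_power < 1.0):
        raise ValueError(f"target_power must lie in (alpha, 1), got {target_power}")
    sign = -1.0 if config.intervention.effect_size < 0 else 1.0

    def power_at(magnitude: float) -> PowerEstimate:
        return estimate_power(config.with_effect(sign * magnitude))

    hi = abs(initial_effect) if initial_effect else config.error_model.noise_sd
    iterations = 1
    est_hi = power_at(hi)
    for _ in range(max_doublings):
        if est_hi.power >= target_power:
            break
        hi *= 2.0
        est_hi = power_at(hi)
        iterations += 1
    else:
        raise SimulationError(
            f"no effect magnitude up to {hi} reaches power {target_power}; "
            "the scenario may be too noisy or too short"
        )

    lo = 0.0
    best, best_est = hi, est_hi
    while hi - lo > effect_tol:
        mid = 0.5 * (lo + hi)
        est = power_at(mid)
        iterations += 1
        if abs(est.power - target_power) <= abs(best_est.power - target_power):
            best, best_est = mid, est
        if abs(est.power - target_power) <= power_tol:
            best, best_est = mid, est
            break
        if est.power < target_power:
            lo = mid
        else:
            hi = mid

    return MDEResult(
        effect=sign * best,
        achieved_power=best_est,
        target_power=target_power,
        tolerance=power_tol,
        iterations=iterations,
    )
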