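# Methods

## Model and procedure

`itspower` estimates the statistical power of an interrupted time-series
(ITS) analysis by Monte Carlo simulation. One replicate consists of three
steps:

1. **Simulate** an outcome series of length *t* from an explicit
   data-generating process (DGP),
2. **fit** the analysis model — an ARIMA(p, d, q) regression with the
   intervention regressor (and optional covariate / linear-time columns) as
   exogenous variables,
3. **test** the intervention coefficient with a two-sided Wald z test at
   level α.

Power is the fraction of replicates with p < α; the binomial Monte Carlo
standard error `sqrt(p(1−p)/n)` quantifies simulation noise. The minimal
detectable effect (MDE) inverts this map: the smallest |effect| whose
power reaches a target, found by bracket expansion and bisection.

### Data-generating process

The simulated outcome is an exact element-wise sum

    y = b0 + b1·x + b2·c + trend + e

* **Errors** `e`: stationary ARMA(p, q) with Gaussian innovations of
  standard deviation `noise_sd`. The recursion is initialised with a
  burn-in of `max(200, 10·(p+q+1))` discarded points so the retained
  segment is a draw from the stationary distribution. Stationarity and
  invertibility are enforced by characteristic-root checks (moduli > 1),
  not merely the (−1, 1) box constraint, which is insufficient above
  order 1.
* **Intervention regressor** `x`: timepoints are 1..t and the intervention
  lands at k+1. Step: 0 up to k, then 1. Pulse: 1 for `pulse_duration`
  points from k+1, then 0. Change in trend: 0 up to k, then 1, 2, 3, …
  so b1 is the change in per-timepoint slope.
* **Covariate** `c`: AR(1) with lag-one correlation 0.5. Its `sd`
  parameter is the *marginal* standard deviation (the innovation SD is
  scaled by `sqrt(1−0.25)`), since that is the observable moment a user
  would estimate from data; `shift_after_k` adds a level change from k+1
  onward, making the covariate a genuine confounder of the intervention.
  A fresh covariate realisation is drawn per replicate — it is part of the
  stochastic DGP, not a fixed design column.
* **Baseline trend**: deterministic, `magnitude·(0, 1, …, t−1)` so the
  intercept is the level at the first timepoint; or stochastic,
  `magnitude` times the cumulative sum of N(0, `stochastic_innov_sd`)
  increments. The error-model differencing order d never applies to data
  generation — integration enters the DGP only through the stochastic
  trend.
* **Log scale**: with `log_scale` the same arithmetic holds with every
  coefficient read on the log scale; a coefficient b corresponds to a
  multiplicative effect exp(b) on the original outcome.

### Analysis model

The regressor matrix always contains the intervention column; the
covariate column iff the scenario models it (`include_in_model`); and a
linear time column (1..t) iff the baseline trend is handled as an
exogenous regressor. For a change-in-trend intervention the tested
coefficient is always the slope-change column, with the baseline time
column (when modelled) absorbing the pre-existing slope.

Estimation is exact Gaussian maximum likelihood. Two routes return the
same optimum:

* **ARIMA(1,0,0)** — the dominant analysis model for ITS — is fitted by
  profiling the regression out of the exact AR(1) likelihood: for each
  candidate autoregressive value φ, a Prais–Winsten transform (first row
  scaled by `sqrt(1−φ²)`, later rows quasi-differenced) whitens the
  errors, so the regression coefficients and innovation variance have
  closed-form maximisers, leaving a one-dimensional concentrated
  likelihood in φ optimised by bounded scalar search. At ~2 ms per fit
  this is what makes 1000-replicate power evaluations and MDE searches
  cheap. A unit test pins this route against the state-space route
  (agreement: φ to ~1e-5, Wald z to ~1e-2).
* **All other orders** use statsmodels' SARIMAX, warm-started from the OLS
  solution of the regression part (which is the exact optimum when
  p = q = 0, giving OLS equivalence to ~1e-9).

Standard errors come from the observed information matrix. The
outer-product-of-gradients default was rejected because it degenerates for
sparse regressors: for a one-timepoint pulse it over-estimates the
standard error threefold (2.57 vs the analytic GLS value 0.894 on a test
series), collapsing pulse power from ~0.63 to ~0.14.

**Differencing** (`trend_model_method="diff"`, or d ≥ 1 in the error
model) differences the response *and* the regressors and drops the
intercept, then fits ARMA(p, q) on the differences. This matches the
convention of R's `arima()`, verified against it directly: the d=1
coefficient equals OLS on differenced data in the no-ARMA case. No time
coefficient is produced — the trend is removed implicitly. Differencing
restores null calibration when the DGP contains a random-walk trend
(rejection ~0.04 vs ~0.37 when the trend is ignored), but it costs a lot
of power for step effects, whose differenced regressor is a single
impulse.

### Monte Carlo machinery

Replicate random streams are spawned from the master seed
(`numpy.random.SeedSequence`), so results are independent of execution
order and bit-identical across reruns. Non-converged fits are excluded
from the power denominator and counted separately; a scenario with more
than 20% failures raises, since power from the survivors would not be
trustworthy (counting failures as non-rejections would bias power
downward instead). The L-BFGS stops flagged as "non-converged" with an
already-vanished gradient (max |∇| < 1e-2, a line-search rounding
artifact affecting ~3% of trend-change fits) are accepted as converged;
their p-values are identical to a converged refit.

The MDE search doubles an upper bracket from a noise-scaled initial guess
until power exceeds the target, then bisects. All evaluations share the
master seed (common random numbers), which makes the empirical power
curve monotone under the shared draws and stabilises the bisection. The
search stops when the bracket is narrower than 0.05 effect units or an
evaluation lands within 0.01 of the target power — below one binomial SE
at n = 1000, so the bracket-width criterion, not sampling noise, normally
ends the search.

Lookup tables fix the conventions of published ITS power grids:
intercept 0, intervention at ⌊t/2⌋, series lengths ≥ 20 (shorter series
give unstable autoregressive estimates), pulse duration 1, and — for
change-in-trend tables — a zero-slope deterministic baseline trend
modelled as a time regressor, so the analysis adjusts for a baseline
slope exactly as a practitioner would. Cells are simulated independently
with per-cell seeds derived from (master seed, t, effect), so any subset
regenerates identically. Because sampling noise can produce small
non-monotone wiggles, `LookupTable.monotonicity_violations` flags only
decreases beyond 3 combined standard errors.

## Parameters that matter

| parameter | units | default | why |
|---|---|---|---|
| `t`, `k` | timepoints | — | design size; intervention at k+1 |
| `noise_sd` | outcome units | 1.0 | innovation SD; the main power determinant besides t |
| `ar_coefs` | — | (0.5,) in examples | AR(1)=0.5 is the common empirical default for ITS outcomes |
| `alpha` | — | 0.05 | two-sided Wald test level |
| `n_sims` | replicates | 1000 | mc_se ≈ 0.013 at power 0.8 |
| `target_power` | — | 0.80 | conventional planning standard |

## What the simulations do and do not show

The generator emulates aggregated continuous outcomes with Gaussian,
serially correlated errors, a single intervention, at most one covariate,
and regular sampling with complete data. Real series bring seasonality,
non-Gaussian and heteroscedastic noise, gradual-onset (transfer-function)
effects, multiple interacting covariates and missing observations — none
of which are modelled here. Passing tests therefore show that the
pipeline is a correct Monte Carlo implementation of *this* DGP/analysis
pairing, not that a particular real data set enjoys the computed power.

Known calibration limits of the analysis model itself (not of the
simulator): maximum-likelihood ARIMA over-rejects in small samples and
near the unit root — type-I error ≈ 0.06–0.07 at t = 200 with AR(1) = 0.5,
≈ 0.10–0.14 at t = 40, ≈ 0.08 at t = 200 with AR(1) = 0.9. R's `arima()`
reproduces these rates, so they are properties of the estimator every ITS
analyst actually uses, and the power the simulator reports is the power of
that real-world procedure, slightly flattered by its anticonservativeness
in those regimes. The test suite asserts calibration where the method is
calibrated and documents the inflation where it is not.

## Problem sizes

Defaults were chosen so a full verification run stays desk-scale: power
estimates use 1000 replicates (2000 for the null-calibration check);
MDE searches use 1000 replicates per evaluation and typically 6–9
evaluations. The complete acceptance recomputation takes on the order of
a minute on one CPU thanks to the profiled AR(1) likelihood.
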