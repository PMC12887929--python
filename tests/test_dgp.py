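"""Data-generating process: component generators and their exact/limit properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from itspower import (
    CovariateSpec,
    ErrorModelSpec,
    InterventionSpec,
    ScenarioConfig,
    TrendSpec,
    ValidationError,
    assemble_series,
    build_baseline_trend,
    build_intervention_regressor,
    simulate_arma_errors,
    simulate_covariate,
    validate_error_model,
)


class TestErrorModelValidation:
    @pytest.mark.parametrize(
        "ar, ma",
        [
            ((0.5,), ()),
            ((), (0.5,)),
            ((0.6, 0.3), ()),  # roots outside unit circle
            ((-0.9,), (0.9,)),
        ],
    )
    def test_accepts_stationary_invertible(self, ar, ma):
        spec = ErrorModelSpec(ar_coefs=ar, ma_coefs=ma)
        assert validate_error_model(spec) is spec

    @pytest.mark.parametrize(
        "ar, ma",
        [
            ((1.0,), ()),  # boundary excluded
            ((-1.0,), ()),
            ((), (1.0,)),
            # box constraints hold but a characteristic root lies inside the
            # unit circle (1 - 0.6z - 0.5z^2 has a root of modulus 0.936)
            ((0.6, 0.5), ()),
            ((), (0.9, -0.95)),
        ],
    )
    def test_rejects_nonstationary_or_noninvertible(self, ar, ma):
        with pytest.raises(ValidationError, match="AR|MA"):
            validate_error_model(ErrorModelSpec(ar_coefs=ar, ma_coefs=ma))

    def test_rejects_nonpositive_noise_sd(self):
        with pytest.raises(ValidationError, match="noise_sd"):
            validate_error_model(ErrorModelSpec(noise_sd=0.0))


class TestArmaErrors:
    def test_white_noise_sample_sd(self, rng):
        e = simulate_arma_errors(ErrorModelSpec(noise_sd=1.0), 10**5, rng)
        assert e.std() == pytest.approx(1.0, abs=0.01)

    def test_ar1_matches_closed_form_moments(self, rng):
        """AR(1) phi=0.5, sigma=1: variance sigma^2/(1-phi^2), lag-1 ACF = phi."""
        e = simulate_arma_errors(ErrorModelSpec(ar_coefs=(0.5,)), 10**5, rng)
        assert e.var() == pytest.approx(1.0 / 0.75, rel=0.03)
        acf1 = np.corrcoef(e[:-1], e[1:])[0, 1]
        assert acf1 == pytest.approx(0.5, abs=0.02)

    def test_ma1_lag1_autocorrelation(self, rng):
        """MA(1) theta: ACF(1) = theta / (1 + theta^2)."""
        theta = 0.6
        e = simulate_arma_errors(ErrorModelSpec(ma_coefs=(theta,)), 10**5, rng)
        acf1 = np.corrcoef(e[:-1], e[1:])[0, 1]
        assert acf1 == pytest.approx(theta / (1 + theta**2), abs=0.02)

    def test_burn_in_leaves_segment_stationary(self, rng):
        """First and last halves of a long AR(1) draw have comparable variance."""
        e = simulate_arma_errors(ErrorModelSpec(ar_coefs=(0.9,)), 4 * 10**4, rng)
        half = len(e) // 2
        assert e[:half].var() == pytest.approx(e[half:].var(), rel=0.15)


class TestInterventionRegressor:
    @pytest.mark.parametrize(
        "kind, t, k, dur, expected",
        [
            ("step", 6, 3, 1, [0, 0, 0, 1, 1, 1]),
            ("pulse", 6, 3, 2, [0, 0, 0, 1, 1, 0]),
            ("pulse", 6, 3, 1, [0, 0, 0, 1, 0, 0]),
            ("trend_change", 6, 3, 1, [0, 0, 0, 1, 2, 3]),
        ],
    )
    def test_coding(self, kind, t, k, dur, expected):
        x = build_intervention_regressor(kind, t, k, dur)
        np.testing.assert_array_equal(x, expected)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValidationError):
            build_intervention_regressor("ramp", 10, 5)

    @given(
        t=st.integers(5, 300),
        data=st.data(),
    )
    @settings(max_examples=50, deadline=None)
    def test_regressor_mass(self, t, data):
        """step sums to t-k; pulse sums to its duration; trend_change ends at t-k."""
        k = data.draw(st.integers(1, t - 2))
        dur = data.draw(st.integers(1, t - k))
        assert build_intervention_regressor("step", t, k).sum() == t - k
        assert build_intervention_regressor("pulse", t, k, dur).sum() == dur
        assert build_intervention_regressor("trend_change", t, k)[-1] == t - k


class TestCovariate:
    def test_zero_sd_gives_constant_with_shift(self, rng):
        spec = CovariateSpec(mean=7.0, sd=0.0, shift_after_k=2.0, include_in_dgp=True)
        x = simulate_covariate(spec, t=10, k=4, rng=rng)
        np.testing.assert_allclose(x[:4], 7.0)
        np.testing.assert_allclose(x[4:], 9.0)

    def test_marginal_moments_and_shift(self, rng):
        """Mean 10, SD 3, shift 1 after the midpoint of a long series."""
        t, k = 10**5, 5 * 10**4
        spec = CovariateSpec(mean=10.0, sd=3.0, shift_after_k=1.0, include_in_dgp=True)
        x = simulate_covariate(spec, t, k, rng)
        assert x[:k].mean() == pytest.approx(10.0, abs=0.05)
        assert x[k:].mean() == pytest.approx(11.0, abs=0.05)
        assert x[:k].std() == pytest.approx(3.0, rel=0.03)

    def test_lag1_autocorrelation_is_half(self, rng):
        spec = CovariateSpec(mean=0.0, sd=1.0, include_in_dgp=True)
        x = simulate_covariate(spec, 10**5, 1, rng)
        acf1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert acf1 == pytest.approx(0.5, abs=0.02)


class TestBaselineTrend:
    def test_deterministic_slope(self, rng):
        spec = TrendSpec(kind="deterministic", magnitude=-0.13, include_in_dgp=True)
        np.testing.assert_allclose(
            build_baseline_trend(spec, 4, rng), [0.0, -0.13, -0.26, -0.39]
        )

    def test_zero_magnitude_stochastic_is_flat(self, rng):
        spec = TrendSpec(kind="stochastic", magnitude=0.0, stochastic_innov_sd=1.0,
                         include_in_dgp=True)
        np.testing.assert_array_equal(build_baseline_trend(spec, 50, rng), 0.0)

    def test_random_walk_variance_grows_linearly(self, rng):
        """Var of the walk at time T is T * innov_sd^2."""
        spec = TrendSpec(kind="stochastic", magnitude=1.0, stochastic_innov_sd=1.0,
                         include_in_dgp=True)
        T = 200
        finals = np.array(
            [build_baseline_trend(spec, T, rng)[-1] for _ in range(2000)]
        )
        assert finals.var() == pytest.approx(T, rel=0.15)


class TestAssembleSeries:
    def test_intercept_only(self, rng):
        cfg = ScenarioConfig(
            t=20, k=10, b0=36.0,
            error_model=ErrorModelSpec(noise_sd=1e-9),
        )
        s = assemble_series(cfg, rng)
        np.testing.assert_allclose(s.y, 36.0, atol=1e-6)

    def test_step_effect_exact(self, rng):
        cfg = ScenarioConfig(
            t=6, k=3,
            intervention=InterventionSpec(kind="step", effect_size=2.0),
            error_model=ErrorModelSpec(noise_sd=1e-12),
        )
        s = assemble_series(cfg, rng)
        np.testing.assert_allclose(s.y, [0, 0, 0, 2, 2, 2], atol=1e-9)

    def test_log_scale_multiplicative_effect(self, rng):
        """log-scale b1 = log(1.10) yields a 10% jump on the original scale."""
        cfg = ScenarioConfig(
            t=40, k=20, b0=np.log(100.0),
            intervention=InterventionSpec(kind="step", effect_size=np.log(1.10)),
            error_model=ErrorModelSpec(noise_sd=1e-10),
            log_scale=True,
        )
        s = assemble_series(cfg, rng)
        ratio = np.exp(s.y[20:].mean()) / np.exp(s.y[:20].mean())
        assert ratio == pytest.approx(1.10, rel=1e-6)

    def test_additive_decomposition_is_exact(self, rng):
        cfg = ScenarioConfig(
            t=80, k=40, b0=5.0,
            intervention=InterventionSpec(kind="trend_change", effect_size=0.3),
            covariate=CovariateSpec(beta=0.5, mean=2.0, sd=1.0, shift_after_k=0.5,
                                    include_in_dgp=True, include_in_model=True),
            trend=TrendSpec(kind="stochastic", magnitude=0.7, stochastic_innov_sd=0.4,
                            include_in_dgp=True),
            error_model=ErrorModelSpec(ar_coefs=(0.4,), ma_coefs=(0.2,)),
        )
        s = assemble_series(cfg, rng)
        reconstructed = (
            cfg.b0
            + cfg.intervention.effect_size * s.intervention_regressor
            + cfg.covariate.beta * s.covariate_values
            + s.trend_values
            + s.errors
        )
        np.testing.assert_allclose(s.y, reconstructed, rtol=0, atol=1e-12)

    def test_determinism_bit_identical(self):
        cfg = ScenarioConfig(
            t=50, k=25,
            intervention=InterventionSpec(kind="step", effect_size=1.0),
            covariate=CovariateSpec(beta=1.0, mean=0.0, sd=1.0, include_in_dgp=True),
            error_model=ErrorModelSpec(ar_coefs=(0.5,)),
        )
        a = assemble_series(cfg, np.random.default_rng(7))
        b = assemble_series(cfg, np.random.default_rng(7))
        np.testing.assert_array_equal(a.y, b.y)

    def test_outcome_invariant_to_unused_covariate_fields(self):
        base = ScenarioConfig(t=50, k=25, error_model=ErrorModelSpec(ar_coefs=(0.5,)))
        other = ScenarioConfig(
            t=50, k=25,
            covariate=CovariateSpec(beta=99.0, mean=50.0, sd=9.0, include_in_dgp=False),
            error_model=ErrorModelSpec(ar_coefs=(0.5,)),
        )
        a = assemble_series(base, np.random.default_rng(3))
        b = assemble_series(other, np.random.default_rng(3))
        np.testing.assert_array_equal(a.y, b.y)

    def test_tidy_frame_columns(self, rng):
        cfg = ScenarioConfig(
            t=30, k=10,
            covariate=CovariateSpec(beta=1.0, sd=1.0, include_in_dgp=True),
            trend=TrendSpec(kind="deterministic", magnitude=0.1, include_in_dgp=True),
        )
        frame = assemble_series(cfg, rng).to_frame()
        assert list(frame.columns) == ["time", "y", "intervention", "covariate", "trend", "error"]
        assert len(frame) == 30


class TestScenarioValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(t=10, k=9),  # k > t-2
            dict(t=10, k=0),
            dict(t=10, k=5, alpha=1.5),
            dict(t=10, k=5, n_sims=0),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            ScenarioConfig(**kwargs)

    def test_pulse_must_fit_in_series(self):
        with pytest.raises(ValidationError, match="pulse"):
            ScenarioConfig(
                t=10, k=8,
                intervention=InterventionSpec(kind="pulse", effect_size=1.0,
                                              pulse_duration=5),
            )

    def test_modelled_covariate_requires_generated_covariate(self):
        with pytest.raises(ValidationError, match="covariate"):
            ScenarioConfig(
                t=20, k=10,
                covariate=CovariateSpec(include_in_dgp=False, include_in_model=True),
            )
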