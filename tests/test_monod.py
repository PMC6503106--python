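"""Monod rate law, growth-rate calculus, and kinetic-constant fitting."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.base import clone

import chemofilm as cf
from chemofilm.exceptions import EstimationError
from chemofilm.monod import MonodCurveFit, TimedDensitySeries


class TestMonodRate:
    def test_half_saturation_definition(self, reference_params):
        assert cf.monod_rate(reference_params.Ks, reference_params) == pytest.approx(
            reference_params.mu_max / 2
        )

    def test_zero_substrate_zero_rate(self, reference_params):
        assert cf.monod_rate(0.0, reference_params) == 0.0

    def test_rate_at_bench_inflow_concentration(self, reference_params):
        # 1.07 * 0.06 / 0.079; this is also the washout bound for Case 2
        assert cf.monod_rate(0.06, reference_params) == pytest.approx(0.8127, abs=5e-5)

    def test_negative_substrate_rejected(self, reference_params):
        with pytest.raises(ValueError):
            cf.monod_rate(-0.1, reference_params)
        with pytest.raises(ValueError):
            cf.monod_rate(np.array([0.1, -0.1]), reference_params)

    @given(st.floats(0, 100, allow_nan=False), st.floats(0, 100))
    def test_monotone_and_bounded(self, s1, s2):
        params = cf.REFERENCE_PARAMS
        lo, hi = sorted((s1, s2))
        r_lo, r_hi = cf.monod_rate(lo, params), cf.monod_rate(hi, params)
        assert r_lo <= r_hi <= params.mu_max


class TestSpecificGrowthRate:
    def test_bench_assay_pair(self):
        # sparse-monolayer assay: 4.36e5 -> 3.78e6 cells/cm^2 over 24 h
        assert cf.specific_growth_rate(4.36e5, 0, 3.78e6, 24) == pytest.approx(0.09, abs=5e-3)

    def test_no_change_is_zero(self):
        assert cf.specific_growth_rate(2.0, 1.0, 2.0, 5.0) == 0.0

    def test_doubling_in_one_hour(self):
        assert cf.specific_growth_rate(1.0, 0.0, 2.0, 1.0) == pytest.approx(math.log(2))

    @given(
        st.floats(1e-6, 1e6), st.floats(0.01, 100), st.floats(-2, 2), st.floats(0, 50)
    )
    def test_exponential_identity(self, x, dt, mu, t0):
        assert cf.specific_growth_rate(
            x, t0, x * math.exp(mu * dt), t0 + dt
        ) == pytest.approx(mu, abs=1e-7)

    @pytest.mark.parametrize(
        "args", [(0.0, 0, 1.0, 1), (1.0, 0, -1.0, 1), (1.0, 1, 2.0, 1), (1.0, 2, 2.0, 1)]
    )
    def test_domain_errors(self, args):
        with pytest.raises(ValueError):
            cf.specific_growth_rate(*args)


class TestDoublingTime:
    @pytest.mark.parametrize("mu, expected", [(0.09, 7.7), (0.28, 2.5), (0.81, 0.9)])
    def test_bench_dilution_rates(self, mu, expected):
        assert round(cf.doubling_time(mu), 1) == expected

    def test_ln2_rate_doubles_hourly(self):
        assert cf.doubling_time(math.log(2)) == pytest.approx(1.0)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            cf.doubling_time(0.0)

    def test_at_half_saturation(self, reference_params):
        # doubling_time(mu(Ks)) = 2 ln2 / mu_max
        mu = cf.monod_rate(reference_params.Ks, reference_params)
        assert cf.doubling_time(mu) == pytest.approx(
            2 * math.log(2) / reference_params.mu_max
        )


class TestMaxSpecificGrowthRate:
    def test_pure_exponential_any_window(self):
        t = np.arange(0, 5, 0.5)
        series = TimedDensitySeries(times=t, values=0.01 * np.exp(0.5 * t))
        for window in (2, 3, 5):
            assert cf.max_specific_growth_rate(series, window) == pytest.approx(0.5)

    def test_constant_series_zero(self):
        series = TimedDensitySeries(times=np.arange(4.0), values=np.ones(4))
        assert cf.max_specific_growth_rate(series) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_window_scan(self):
        rng = np.random.default_rng(7)
        t = np.arange(0, 8, 0.5)
        values = 0.01 * np.exp(0.4 * t) * np.exp(rng.normal(0, 0.03, t.size))
        series = TimedDensitySeries(times=t, values=values)
        w = 3
        brute = max(
            np.polyfit(t[i : i + w], np.log(values[i : i + w]), 1)[0]
            for i in range(t.size - w + 1)
        )
        assert cf.max_specific_growth_rate(series, w) == pytest.approx(brute)

    def test_early_phase_slope_approximates_monod_rate(self, reference_params):
        """Noiseless batch curves start at the substrate-set Monod rate."""
        spec = cf.SyntheticSpec(noise_cv=0.0, seed=0)
        for series in cf.gen_batch_series(spec):
            mu_hat = cf.max_specific_growth_rate(series, window=3)
            mu_true = cf.monod_rate(series.dilution, reference_params)
            assert mu_hat == pytest.approx(mu_true, rel=0.02)

    def test_series_shorter_than_window(self):
        series = TimedDensitySeries(times=np.array([0.0, 1.0]), values=np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            cf.max_specific_growth_rate(series, window=3)
        with pytest.raises(ValueError):
            cf.max_specific_growth_rate(series, window=1)


class TestFitMonod:
    S_LEVELS = np.array([1, 1 / 2, 1 / 4, 1 / 8, 1 / 16, 1 / 64, 1 / 128])

    def test_exact_inversion_on_noiseless_points(self, reference_params):
        mu = cf.monod_rate(self.S_LEVELS, reference_params)
        fitted = cf.fit_monod(self.S_LEVELS, mu)
        assert fitted.mu_max == pytest.approx(1.07, rel=1e-12)
        assert fitted.Ks == pytest.approx(0.019, rel=1e-12)

    def test_two_exact_points(self, reference_params):
        S = np.array([0.01, 0.5])
        fitted = cf.fit_monod(S, cf.monod_rate(S, reference_params))
        assert fitted.mu_max == pytest.approx(1.07, rel=1e-10)
        assert fitted.Ks == pytest.approx(0.019, rel=1e-10)

    def test_growth_observation_input(self, reference_params):
        obs = [cf.GrowthObservation(s, cf.monod_rate(s, reference_params)) for s in self.S_LEVELS]
        fitted = cf.fit_monod(obs)
        assert fitted.mu_max == pytest.approx(1.07, rel=1e-10)

    def test_noisy_fit_recovers_within_calibrated_tolerance(self, reference_params):
        rng = np.random.default_rng(42)
        sigma2 = math.log(1 + 0.05**2)
        S = np.repeat(self.S_LEVELS, 20)
        mu = cf.monod_rate(S, reference_params) * np.exp(
            rng.normal(0, math.sqrt(sigma2), S.size) - sigma2 / 2
        )
        fitted = cf.fit_monod(S, mu)
        assert fitted.mu_max == pytest.approx(1.07, rel=0.05)
        assert fitted.Ks == pytest.approx(0.019, rel=0.15)

    def test_zero_points_excluded_with_count(self, reference_params):
        S = np.concatenate([[0.0], self.S_LEVELS])
        mu = np.concatenate([[0.0], cf.monod_rate(self.S_LEVELS, reference_params)])
        est = MonodCurveFit().fit(S, mu)
        assert est.n_excluded_ == 1
        assert est.n_points_ == len(self.S_LEVELS)

    def test_non_saturating_data_raises(self):
        # rate decreasing with substrate: reciprocal line has negative slope
        with pytest.raises(EstimationError):
            cf.fit_monod(np.array([1.0, 2.0]), np.array([1.0, 0.5]))

    def test_too_few_points_raises(self):
        with pytest.raises(EstimationError):
            cf.fit_monod(np.array([0.5]), np.array([0.9]))
        with pytest.raises(EstimationError):
            cf.fit_monod(np.array([0.5, 0.5]), np.array([0.9, 0.9]))

    def test_nls_refit_matches_on_exact_data(self, reference_params):
        mu = cf.monod_rate(self.S_LEVELS, reference_params)
        fitted = cf.fit_monod(self.S_LEVELS, mu, method="nls")
        assert fitted.mu_max == pytest.approx(1.07, rel=1e-6)
        assert fitted.Ks == pytest.approx(0.019, rel=1e-6)

    def test_sklearn_estimator_contract(self, reference_params):
        est = MonodCurveFit(method="nls", Y=0.5)
        assert est.get_params() == {"method": "nls", "Y": 0.5}
        est = clone(est).set_params(method="reciprocal")
        mu = cf.monod_rate(self.S_LEVELS, reference_params)
        est.fit(self.S_LEVELS.reshape(-1, 1), mu)
        np.testing.assert_allclose(est.predict(self.S_LEVELS), mu, rtol=1e-10)
        report = est.fit_report()
        assert report["n_points"] == len(self.S_LEVELS)
        assert report["r_squared"] == pytest.approx(1.0)
        assert est.params_.Y == 0.5
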