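"""Centered polynomial fitting, degree selection, confidence bands,
derivative-root extrema, and the labeling-period statistic."""

import numpy as np
import pytest
from numpy.polynomial import polynomial as P
from scipy import stats

from tests.conftest import make_normalized
from thymitrace.enrichment_kinetics import (
    CenteredPolynomialFit,
    ExtrapolationWarning,
    SingularFitError,
    _crossing_interval,
    confidence_band,
    find_extrema,
    fit_centered_polynomial,
    labeling_period,
    select_degree,
    summarize_patient,
)
from thymitrace.study_ingest import CohortConfig
from thymitrace.synthetic_data import TracerKineticsParams, enrichment_curve


class TestFit:
    def test_noiseless_cubic_exact_recovery(self):
        t = np.linspace(0, 20, 10)
        c = t.mean()
        y = 2 + 0.5 * (t - c) - 0.1 * (t - c) ** 3
        fit = fit_centered_polynomial(t, y, 3)
        assert fit.coefficients == pytest.approx([2.0, 0.5, 0.0, -0.1], abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        t = rng.uniform(0, 24, 30)
        y = rng.normal(1.0, 0.5, 30)
        fit = fit_centered_polynomial(t, y, 3)
        # independent brute-force (X'X)^-1 X'y solution
        X = np.column_stack([(t - t.mean()) ** k for k in range(4)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.coefficients == pytest.approx(beta, abs=1e-6)
        resid = y - X @ beta
        assert fit.r_squared == pytest.approx(
            1 - resid @ resid / np.sum((y - y.mean()) ** 2), abs=1e-10
        )

    def test_fitted_values_invariant_to_time_shift(self, rng):
        t = rng.uniform(0, 24, 20)
        y = rng.normal(1.0, 0.3, 20)
        f1 = fit_centered_polynomial(t, y, 3)
        f2 = fit_centered_polynomial(t + 100.0, y, 3)
        assert f1.predict(t) == pytest.approx(f2.predict(t + 100.0), abs=1e-8)

    def test_r_squared_nondecreasing_in_degree(self, rng):
        t = rng.uniform(0, 24, 25)
        y = rng.normal(1.0, 0.3, 25)
        r2 = [fit_centered_polynomial(t, y, d).r_squared for d in range(1, 7)]
        assert all(b >= a - 1e-12 for a, b in zip(r2, r2[1:]))

    def test_rank_deficient_design_raises(self):
        with pytest.raises(SingularFitError):
            fit_centered_polynomial([1.0, 1.0, 2.0, 2.0, 2.0, 1.0], np.ones(6), 3)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            fit_centered_polynomial([0, 1, 2, 3], [1, 2, 3, 4], 3)


class TestSelectDegree:
    def test_exact_cubic_selects_three(self):
        # every order up to 3 contributes, so R² gains stay above the
        # plateau threshold until the exact degree is reached
        t = np.linspace(0, 24, 15)
        u = t - 12
        y = 1 + 0.4 * u + 0.08 * u**2 - 0.02 * u**3
        degree, table = select_degree(t, y)
        assert degree == 3
        assert list(table["degree"]) == [1, 2, 3, 4, 5, 6]
        assert table["r_squared"].iloc[2] == pytest.approx(1.0, abs=1e-10)

    def test_exact_linear_selects_one(self):
        t = np.linspace(0, 24, 15)
        degree, _ = select_degree(t, 0.2 + 0.05 * t)
        assert degree == 1

    def test_matches_brute_force_gain_scan(self, rng):
        params = TracerKineticsParams()
        t = np.sort(rng.uniform(0, 24, 40))
        y = enrichment_curve(t, params, dose_times=[0.0]) + rng.normal(0, 0.1, 40)
        eps = 0.01
        degree, _ = select_degree(t, y, plateau_epsilon=eps)
        r2 = {d: fit_centered_polynomial(t, y, d).r_squared for d in range(1, 7)}
        expected = 6
        for d in range(1, 6):
            if r2[d + 1] - r2[d] < eps:
                expected = d
                break
        assert degree == expected


class TestConfidenceBand:
    def test_zero_residual_variance_collapses_band(self):
        t = np.linspace(0, 20, 10)
        y = 1 + 0.1 * (t - t.mean())
        fit = fit_centered_polynomial(t, y, 1)
        band = confidence_band(fit, np.linspace(0, 20, 50))
        assert band.lower == pytest.approx(band.mean, abs=1e-8)
        assert band.upper == pytest.approx(band.mean, abs=1e-8)

    def test_halfwidth_at_center_is_intercept_se(self, rng):
        # at t = center the basis is (1, 0, ..., 0) so the half-width is
        # the t-quantile times sqrt(var(b0))
        t = rng.uniform(0, 24, 20)
        y = rng.normal(1.0, 0.3, 20)
        fit = fit_centered_polynomial(t, y, 3)
        band = confidence_band(fit, [fit.center])
        expected = stats.t.ppf(0.975, fit.dof) * np.sqrt(
            fit.coefficient_covariance[0, 0]
        )
        assert (band.upper[0] - band.mean[0]) == pytest.approx(expected, rel=1e-10)

    def test_band_ordering_and_width_minimal_near_center(self, rng):
        t = rng.uniform(0, 24, 30)
        y = rng.normal(1.0, 0.3, 30)
        fit = fit_centered_polynomial(t, y, 3)
        grid = np.linspace(0, 24, 200)
        band = confidence_band(fit, grid)
        assert np.all(band.lower <= band.mean + 1e-12)
        assert np.all(band.mean <= band.upper + 1e-12)
        width = band.upper - band.lower
        # narrowest near the data center, widest at the edges
        assert width.argmin() not in (0, len(grid) - 1)

    def test_extrapolation_warning(self, rng):
        t = rng.uniform(0, 10, 15)
        fit = fit_centered_polynomial(t, rng.normal(size=15), 2)
        with pytest.warns(ExtrapolationWarning):
            confidence_band(fit, [100.0])

    def test_two_se_variant_uses_fixed_multiplier(self, rng):
        t = rng.uniform(0, 24, 10)
        y = rng.normal(1.0, 0.3, 10)
        fit = fit_centered_polynomial(t, y, 3)
        band = confidence_band(fit, [fit.center], method="2se")
        assert band.critical == 2.0


class TestFindExtrema:
    def test_linear_fit_extrema_at_endpoints(self):
        t = np.linspace(0, 20, 10)
        fit = fit_centered_polynomial(t, 0.5 + 0.1 * t, 1)
        ext = find_extrema(fit, (0.0, 20.0))
        assert ext.time_of_min == pytest.approx(0.0)
        assert ext.time_of_max == pytest.approx(20.0)

    def test_analytic_cubic_interior_maximum(self):
        # y = b0 + 0.5 u - 0.1 u^3 about center c: derivative root at
        # u = sqrt(5/3), solved by hand
        t = np.linspace(0, 20, 12)
        c = t.mean()
        y = 1.0 + 0.5 * (t - c) - 0.1 * (t - c) ** 3
        fit = fit_centered_polynomial(t, y, 3)
        # support covering both derivative roots but excluding the far
        # cubic tails, so the interior extrema are the global ones
        ext = find_extrema(fit, (c - 2.0, c + 2.0))
        u_star = np.sqrt(5.0 / 3.0)
        assert ext.time_of_max == pytest.approx(c + u_star, abs=1e-6)
        assert ext.max_value == pytest.approx(
            1.0 + 0.5 * u_star - 0.1 * u_star**3, abs=1e-8
        )
        assert ext.time_of_min == pytest.approx(c - u_star, abs=1e-6)

    def test_negation_swaps_max_and_min(self, rng):
        t = rng.uniform(0, 24, 20)
        y = rng.normal(1.0, 0.4, 20)
        f1 = fit_centered_polynomial(t, y, 3)
        f2 = fit_centered_polynomial(t, -y, 3)
        e1 = find_extrema(f1, (0.0, 24.0))
        e2 = find_extrema(f2, (0.0, 24.0))
        assert e1.time_of_max == pytest.approx(e2.time_of_min, abs=1e-8)
        assert e1.max_value == pytest.approx(-e2.min_value, abs=1e-8)

    def test_agrees_with_dense_grid_search(self, rng):
        for _ in range(100):
            coeffs = rng.normal(0, 1, 4)
            fit = CenteredPolynomialFit(
                degree=3, center=12.0, coefficients=coeffs,
                coefficient_covariance=np.eye(4), residual_variance=0.0,
                dof=10, r_squared=1.0, n_obs=14, t_min=0.0, t_max=24.0,
            )
            ext = find_extrema(fit, (0.0, 24.0))
            grid = np.arange(0.0, 24.0 + 1e-9, 1e-3)
            vals = fit.predict(grid)
            assert abs(ext.time_of_max - grid[vals.argmax()]) <= 1e-2
            assert abs(ext.time_of_min - grid[vals.argmin()]) <= 1e-2


class TestLabelingPeriod:
    def test_linear_lower_band_analytic_crossing(self):
        # lower(t) = 0.5 - 0.01 t crosses 0.37 at t = 13 exactly
        start, end, never = _crossing_interval(
            lambda t: 0.5 - 0.01 * np.asarray(t), 0.37, time_of_min=24.0, t_end=24.0
        )
        assert not never
        assert start == pytest.approx(0.0)
        assert end == pytest.approx(13.0, abs=2e-3)

    def test_band_above_throughout_ends_at_time_of_min(self):
        start, end, never = _crossing_interval(
            lambda t: 1.0 + 0 * np.asarray(t), 0.37, time_of_min=18.2, t_end=24.0
        )
        assert (start, end, never) == (0.0, 18.2, False)

    def test_band_entirely_below_gives_zero(self):
        start, end, never = _crossing_interval(
            lambda t: 0.1 + 0 * np.asarray(t), 0.37, time_of_min=18.2, t_end=24.0
        )
        assert never
        assert end - start == 0.0

    def test_late_start_when_band_begins_below(self):
        # lower(t) = 0.3 + 0.02 t upcrosses 0.37 at t = 3.5, never descends
        start, end, never = _crossing_interval(
            lambda t: 0.3 + 0.02 * np.asarray(t), 0.37, time_of_min=20.0, t_end=24.0
        )
        assert start == pytest.approx(3.5, abs=2e-3)
        assert end == pytest.approx(20.0)

    def test_monotone_nonincreasing_in_baseline(self, rng):
        # with the fallback endpoint fixed at the window end, raising the
        # baseline can only shrink the above-baseline interval
        t = np.sort(rng.uniform(0, 24, 30))
        y = enrichment_curve(t, TracerKineticsParams(amplitude=0.5),
                             dose_times=[0.0]) + rng.normal(0, 0.05, 30)
        fit = fit_centered_polynomial(t, y, 3)
        band = confidence_band(fit, np.linspace(0, 24, 200))
        periods = [
            labeling_period(band, b, time_of_min=24.0)
            for b in (0.2, 0.37, 0.5, 0.8)
        ]
        assert all(b <= a + 1e-9 for a, b in zip(periods, periods[1:]))


class TestSummarizePatient:
    def test_noiseless_sawtooth_sanity(self, config):
        # hourly samples after the last of 5 daily doses: the carryover
        # from earlier doses keeps enrichment above baseline at t = 0
        params = TracerKineticsParams(noise_sd=0.0)
        t = np.tile(np.arange(0.5, 24, 1.0), 2)
        y = enrichment_curve(t + 96.0, params)
        summ = summarize_patient(make_normalized(t, y), config)
        assert summ.labeling_period > 0
        assert summ.peak_value > config.baseline_atom_percent
        assert summ.peak_value >= summ.min_value

    def test_duplicating_samples_keeps_point_estimates(self, config, rng):
        t = np.sort(rng.uniform(0, 24, 20))
        y = enrichment_curve(t, TracerKineticsParams(), dose_times=[0.0])
        y = y + rng.normal(0, 0.1, 20)
        s1 = summarize_patient(make_normalized(t, y), config)
        s2 = summarize_patient(
            make_normalized(np.tile(t, 2), np.tile(y, 2)), config
        )
        # OLS weight-doubling identity: fitted curve unchanged
        assert s2.peak_value == pytest.approx(s1.peak_value, abs=1e-8)
        assert s2.time_to_peak == pytest.approx(s1.time_to_peak, abs=1e-6)
        assert s2.r_squared == pytest.approx(s1.r_squared, abs=1e-10)
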