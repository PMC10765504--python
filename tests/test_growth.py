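import math

import numpy as np
import pytest
from scipy import integrate

from overturnlab import growth
from overturnlab.growth import (
    FitError,
    GrowthFit,
    NoGrowthError,
    bacterial_carbon,
    compute_bge,
    exponential_window,
    fit_logistic,
    integrate_excess,
    interpolate_at,
    logistic,
    specific_growth_rate,
    window_rate,
)

#: per-cell carbon → µmol conversion at 20 fg C per cell
FG20 = 20.0 * 1e-15 / 12.011 * 1e6


class TestFitLogistic:
    def test_noiseless_parameter_recovery(self):
        K, N0, r = 70e8, 5.28e8, 1.2
        t = np.linspace(0, 6, 13)
        fit = fit_logistic(t, logistic(t, K, r, N0))
        assert fit.K == pytest.approx(K, rel=1e-6)
        assert fit.N0 == pytest.approx(N0, rel=1e-6)
        assert fit.r == pytest.approx(r, rel=1e-6)
        # closed-form half-capacity time ln((K−N0)/N0)/r
        assert fit.t_mid == pytest.approx(math.log((K - N0) / N0) / 1.2, rel=1e-6)
        assert fit.t_mid == pytest.approx(2.0885, abs=1e-3)

    def test_stationary_is_twice_t_mid(self):
        t = np.linspace(0, 10, 11)
        fit = fit_logistic(t, logistic(t, 1e9, 0.8, 1e8))
        assert fit.t_stationary == pytest.approx(2 * fit.t_mid)

    def test_constant_series_is_no_growth(self):
        with pytest.raises(NoGrowthError):
            fit_logistic(np.arange(6), np.full(6, 5e8))

    def test_decreasing_series_is_no_growth(self):
        with pytest.raises(NoGrowthError):
            fit_logistic(np.arange(6), 5e8 * np.exp(-0.3 * np.arange(6)))

    def test_too_few_points(self):
        with pytest.raises(FitError, match="≥5"):
            fit_logistic([0, 1, 2], [1.0, 2.0, 3.0])


class TestExponentialWindow:
    def test_monotone_rising_starts_at_zero(self):
        t = np.arange(11.0)
        y = logistic(t, 1e9, 0.9, 1e8)
        fit = fit_logistic(t, y)
        assert exponential_window(t, y, fit)[0] == 0.0

    def test_die_off_starts_at_minimum(self):
        t = np.arange(11.0)
        y = logistic(t, 1e9, 0.9, 1e8)
        y[0] = 3e8  # initial die-off: day 0 above the day-1 minimum
        fit = fit_logistic(t[1:], y[1:])
        assert exponential_window(t, y, fit)[0] == 1.0

    def test_window_ends_at_stationary(self):
        t = np.arange(11.0)
        y = logistic(t, 1e9, 0.9, 1e8)
        fit = fit_logistic(t, y)
        assert exponential_window(t, y, fit)[1] == pytest.approx(fit.t_stationary)


class TestSpecificGrowthRate:
    def test_exact_exponential(self):
        t = np.arange(5.0)
        assert specific_growth_rate(t, 2e8 * np.exp(0.19 * t), (0, 4)) == pytest.approx(0.19)

    def test_flat_log_is_zero(self):
        assert specific_growth_rate(np.arange(5.0), np.full(5, 3.3), (0, 4)) == pytest.approx(0.0)

    def test_two_points_exact_slope(self):
        assert specific_growth_rate([0, 1], [1.0, math.e], (0, 1)) == pytest.approx(1.0)

    def test_nonpositive_value_errors(self):
        with pytest.raises(ValueError, match="log"):
            specific_growth_rate([0, 1, 2], [1.0, 0.0, 2.0], (0, 2))


class TestInterpolateAt:
    def test_midpoint(self):
        assert interpolate_at([0, 2], [10, 20], 1) == 15

    def test_knot_identity(self):
        assert interpolate_at([0, 2, 5], [10, 20, 50], 2) == 20

    def test_extrapolation_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            interpolate_at([0, 2], [10, 20], -1)


class TestIntegrateExcess:
    def test_triangle_above(self):
        t = np.linspace(0, 6, 7)
        v = t / 6.0
        assert integrate_excess(t, v, (0, 6), 0.0, "above") == pytest.approx(3.0)
        assert integrate_excess(t, v, (0, 6), 0.0, "above", normalize=True) == pytest.approx(0.5)

    def test_triangle_below(self):
        t = np.linspace(0, 6, 7)
        v = 100 - 5 * t / 6.0
        assert integrate_excess(t, v, (0, 6), 100.0, "below") == pytest.approx(15.0)

    def test_zero_excess(self):
        t = np.linspace(0, 6, 7)
        assert integrate_excess(t, np.full(7, 42.0), (0, 6), 42.0, "above") == pytest.approx(0.0)

    def test_interpolated_endpoint(self):
        # window end between knots: linear data stays exact
        t = np.array([0.0, 2.0, 4.0])
        v = 2.0 * t
        assert integrate_excess(t, v, (0, 3), 0.0, "above") == pytest.approx(9.0)

    def test_matches_quadrature_oracle_on_smooth_curve(self):
        f = lambda x: 100 - 5 * np.sin(x / 3.0) - 2.0 * x
        t = np.linspace(0, 6, 200)
        trapz = integrate_excess(t, f(t), (0, 6), 0.0, "above")
        exact, _ = integrate.quad(f, 0, 6)
        assert trapz == pytest.approx(exact, rel=0.01)


class TestBacterialCarbon:
    def test_one_billion_cells(self):
        assert bacterial_carbon(1e9) == pytest.approx(1.665, abs=5e-4)

    def test_surface_abundance(self):
        # 17.6e8 cells L⁻¹ at 20 fg C per cell
        assert bacterial_carbon(17.6e8) == pytest.approx(2.93, abs=5e-3)

    def test_zero(self):
        assert bacterial_carbon(0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bacterial_carbon(-1.0)


def _linear_fit(window=(0.0, 6.0)):
    return GrowthFit(K=1e9, r=1.0, N0=1e8, t_mid=3.0, t_stationary=window[1],
                     rss=0.0, window=window)


class TestComputeBge:
    def test_closed_form_triangles(self):
        t = np.linspace(0, 6, 7)
        pa = (t / 6.0) / FG20          # biomass carbon rises linearly 0 → 1 µmol
        doc = 100 - 5 * t / 6.0        # DOC falls linearly 100 → 95
        res = compute_bge(t, pa, t, doc, _linear_fit())
        assert res.integral_bc == pytest.approx(3.0)
        assert res.integral_doc == pytest.approx(15.0)
        assert res.bge == pytest.approx(0.20)
        assert res.bge_percent == pytest.approx(20.0)

    def test_constant_pa_gives_zero(self):
        t = np.linspace(0, 6, 7)
        res = compute_bge(t, np.full(7, 1e8), t, 100 - t, _linear_fit())
        assert res.bge == pytest.approx(0.0)

    def test_constant_doc_flagged_undefined(self):
        t = np.linspace(0, 6, 7)
        res = compute_bge(t, (t / 6.0) / FG20, t, np.full(7, 100.0), _linear_fit())
        assert math.isnan(res.bge)
        assert res.flag == "no net DOC removal"

    def test_invariant_to_doc_offset(self):
        t = np.linspace(0, 6, 7)
        pa = (t / 6.0) / FG20
        doc = 100 - 5 * t / 6.0
        a = compute_bge(t, pa, t, doc, _linear_fit())
        b = compute_bge(t, pa, t, doc + 37.5, _linear_fit())
        assert a.bge == pytest.approx(b.bge)


class TestWindowRate:
    def test_exact_negative_slope(self):
        t = np.arange(8.0)
        assert window_rate(t, 110 - 0.79 * t, 0, 7) == pytest.approx(-0.79)

    def test_constant_is_zero(self):
        assert window_rate(np.arange(5.0), np.full(5, 3.0), 0, 4) == pytest.approx(0.0)

    def test_matches_normal_equation_oracle(self):
        t = np.linspace(-3, 3, 13)
        v = 2.0 + 0.5 * t + 0.3 * t**2
        # brute-force normal equations
        x = np.vstack([np.ones_like(t), t]).T
        beta = np.linalg.solve(x.T @ x, x.T @ v)
        assert window_rate(t, v, -3, 3) == pytest.approx(beta[1])


class TestPipelineRecovery:
    @pytest.mark.parametrize("treatment,mu,duration", [
        ("S/S", 0.03, 10.1), ("S/D", 0.19, 4.9), ("D/S", 0.11, 2.8),
    ])
    def test_noiseless_mu_and_duration_recovery(self, noiseless_bundle,
                                                treatment, mu, duration):
        ts = noiseless_bundle.timeseries
        for bottle in ts.bottles(treatment):
            t, y = ts.series(treatment, bottle, "PA")
            fit = growth.analyze_growth(t, y)
            assert fit.mu == pytest.approx(mu, rel=1e-4)
            assert fit.window[1] - fit.window[0] == pytest.approx(duration, rel=1e-4)

    def test_mu_never_exceeds_r(self, noiseless_bundle):
        ts = noiseless_bundle.timeseries
        for trt in ts.treatments:
            t, y = ts.series(trt, ts.bottles(trt)[0], "PA")
            fit = growth.analyze_growth(t, y)
            assert fit.mu <= fit.r
            assert fit.mu > 0.4 * fit.r  # OLS over the full window stays above ~r/2
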