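"""Unit and property tests for the Patlak graphical-analysis estimators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bbbkinetics.patlak import (
    DegenerateDesignError,
    InsufficientDataError,
    TimeActivitySeries,
    compare_ki,
    detect_linear_phase,
    exposure_time,
    fit_series,
    patlak_fit,
    patlak_transform,
)


def biexp_series(times, a1=100.0, l1=0.2, a2=50.0, l2=0.01, tissue=None):
    t = np.asarray(times, dtype=float)
    cp = a1 * np.exp(-l1 * t) + a2 * np.exp(-l2 * t)
    return TimeActivitySeries(times=t, serum_conc=cp, tissue_per_mass=tissue)


def biexp_integral(t, a1=100.0, l1=0.2, a2=50.0, l2=0.01):
    return (a1 / l1) * (1 - np.exp(-l1 * t)) + (a2 / l2) * (1 - np.exp(-l2 * t))


class TestTimeActivitySeries:
    def test_rejects_duplicate_or_decreasing_times(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            TimeActivitySeries(times=[5, 5, 10], serum_conc=[1, 1, 1])
        with pytest.raises(ValueError, match="strictly increasing"):
            TimeActivitySeries(times=[5, 4, 10], serum_conc=[1, 1, 1])

    def test_rejects_nonpositive_serum(self):
        with pytest.raises(ValueError, match="positive"):
            TimeActivitySeries(times=[1, 2], serum_conc=[1.0, 0.0])

    def test_single_point_rejected(self):
        with pytest.raises(InsufficientDataError):
            TimeActivitySeries(times=[5], serum_conc=[1.0])

    def test_ratio_derived_and_consistency_enforced(self):
        s = TimeActivitySeries(
            times=[1, 2], serum_conc=[2.0, 4.0], tissue_per_mass=[4.0, 4.0]
        )
        np.testing.assert_allclose(s.ratio, [2.0, 1.0])
        with pytest.raises(ValueError, match="inconsistent"):
            TimeActivitySeries(
                times=[1, 2],
                serum_conc=[2.0, 4.0],
                tissue_per_mass=[4.0, 4.0],
                ratio=[2.0, 2.0],
            )


class TestExposureTime:
    @given(
        c=st.floats(0.1, 1e6),
        t=st.sampled_from([5.0, 20.0, 30.0, 45.0, 60.0]),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_constant_serum_identity(self, c, t):
        """Theta(t) = t exactly when Cp is constant, for any positive level."""
        times = np.array([5.0, 20.0, 30.0, 45.0, 60.0])
        s = TimeActivitySeries(times=times, serum_conc=np.full(5, c))
        assert exposure_time(s, t) == pytest.approx(t, rel=1e-12)

    def test_t_zero_is_empty_integral(self):
        s = biexp_series([5, 10, 20])
        assert exposure_time(s, 0.0, back_extrapolate=False) == 0.0
        assert exposure_time(s, 0.0) == 0.0

    def test_biexponential_closed_form(self):
        """Dense trapezoid matches the closed-form biexponential integral.

        For Cp = 100 e^{-0.2T} + 50 e^{-0.01T}, Theta(30) = 48.13 min by the
        closed form ((100/0.2)(1-e^{-6}) + (50/0.01)(1-e^{-0.3})) / Cp(30).
        """
        times = np.arange(0.01, 30.0 + 1e-9, 0.01)
        s = biexp_series(times)
        expected = biexp_integral(30.0) / (
            100 * np.exp(-0.2 * 30) + 50 * np.exp(-0.01 * 30)
        )
        assert expected == pytest.approx(48.13, abs=0.01)  # frozen oracle value
        assert exposure_time(s, 30.0) == pytest.approx(expected, rel=1e-4)

    def test_trapezoid_converges_with_step_halving(self):
        """Error against the closed-form integral falls with each halving in
        the coarse-sampling regime and is negligible at dense sampling.

        (At very fine steps the signed error crosses zero — the interior
        trapezoid overshoot cancels the back-extrapolation undershoot — so
        strict monotonicity is only expected while discretisation dominates.)
        """
        exact = biexp_integral(30.0) / (
            100 * np.exp(-0.2 * 30) + 50 * np.exp(-0.01 * 30)
        )
        errors = []
        for step in (10.0, 5.0, 2.5, 1.25):
            times = np.arange(step, 30.0 + 1e-9, step)
            errors.append(abs(exposure_time(biexp_series(times), 30.0) - exact))
        assert all(b < a for a, b in zip(errors, errors[1:]))
        assert errors[-1] < 1e-2 * exact

    def test_unsampled_time_requires_interpolation(self):
        s = biexp_series([5, 10, 20])
        with pytest.raises(ValueError, match="not a sampled time"):
            exposure_time(s, 7.0)
        assert 0 < exposure_time(s, 7.0, interpolate=True) < exposure_time(
            s, 20.0, interpolate=True
        )
        with pytest.raises(ValueError, match="outside sampled range"):
            exposure_time(s, 25.0, interpolate=True)

    def test_monotone_in_t_for_positive_serum(self):
        s = biexp_series([2, 5, 10, 20, 40])
        vals = [exposure_time(s, t) for t in s.times]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestTransformAndFit:
    def test_constant_ratio_pairs_carried_through(self):
        s = TimeActivitySeries(
            times=[5.0, 10.0],
            serum_conc=[3.0, 3.0],
            tissue_per_mass=[6.0, 6.0],
        )
        x, y = patlak_transform(s)
        np.testing.assert_allclose(x, [5.0, 10.0])
        np.testing.assert_allclose(y, [2.0, 2.0])

    def test_construct_then_recover_on_biexponential(self):
        """Tissue built as Ki*Int(Cp) + Vi*Cp lies exactly on the Patlak line."""
        ki, vi = 0.7, 12.0
        t = np.array([5.0, 20.0, 30.0, 45.0, 60.0])
        cp = 100 * np.exp(-0.2 * t) + 50 * np.exp(-0.01 * t)
        s0 = TimeActivitySeries(times=t, serum_conc=cp)
        from bbbkinetics.patlak import serum_integral

        tissue = ki * serum_integral(s0) + vi * cp
        s = TimeActivitySeries(times=t, serum_conc=cp, tissue_per_mass=tissue)
        x, y = patlak_transform(s)
        np.testing.assert_allclose(y, ki * x + vi, rtol=1e-12)
        fit = patlak_fit(x, y)
        assert fit.ki == pytest.approx(ki, rel=1e-12)
        assert fit.vi == pytest.approx(vi, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_exact_collinear_points(self):
        fit = patlak_fit([0.0, 10.0, 20.0], [10.0, 20.0, 30.0])
        assert fit.ki == pytest.approx(1.0)
        assert fit.vi == pytest.approx(10.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.ki_se == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_design_rejected(self):
        with pytest.raises(DegenerateDesignError):
            patlak_fit([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])

    def test_insufficient_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            patlak_fit([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], phase_window=(10.0, 20.0))

    def test_refit_of_stored_pairs_reproduces_fit(self):
        rng = np.random.default_rng(7)
        x = np.sort(rng.uniform(0, 50, 8))
        y = 0.3 * x + 5 + rng.normal(0, 0.5, 8)
        fit = patlak_fit(x, y)
        refit = patlak_fit(fit.exposure_times, fit.ratios)
        assert refit.ki == fit.ki and refit.vi == fit.vi

    @given(st.integers(0, 1000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_normal_equations_oracle(self, seed):
        """OLS slope/intercept agree with the brute-force normal equations."""
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 12)
        x = np.sort(rng.uniform(0, 100, n))
        if np.ptp(x) == 0:
            x = x + np.arange(n)
        y = rng.normal(0, 10, n)
        fit = patlak_fit(x, y)
        A = np.vstack([x, np.ones_like(x)]).T
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert fit.ki == pytest.approx(beta[0], rel=1e-9, abs=1e-9)
        assert fit.vi == pytest.approx(beta[1], rel=1e-9, abs=1e-9)

    def test_phase_window_restricts_points(self):
        x = np.array([1.0, 5.0, 10.0, 30.0, 50.0])
        y = 2.0 * x + 1.0
        y[-2:] += 100  # late nonlinearity
        fit = patlak_fit(x, y, phase_window=(0.0, 10.0))
        assert fit.n_points == 3
        assert fit.ki == pytest.approx(2.0)


class TestDetectLinearPhase:
    def test_collinear_spans_all_pairs(self):
        x = np.linspace(1, 100, 10)
        res = detect_linear_phase(x, 0.5 * x + 3, max_exposure=None)
        assert res.window == (0.0, 100.0)
        assert res.n_points == 10
        assert not res.warning

    def test_piecewise_slope_break_detected(self):
        """Collinear up to exposure 20, slope halves after: window edge is the
        last pair <= 20 (verified by enumerating all prefixes)."""
        x = np.array([2.0, 6.0, 10.0, 14.0, 18.0, 25.0, 32.0, 40.0])
        y = np.where(x <= 20, 1.0 * x + 5, 25.0 + 0.5 * (x - 20))
        res = detect_linear_phase(x, y, max_exposure=np.inf)
        # independent enumeration of prefix R^2
        def r2(k):
            f = patlak_fit(x[:k], y[:k])
            return f.r_squared
        passing = [k for k in range(3, 9) if r2(k) >= 0.95]
        assert res.n_points == max(passing)
        assert res.window[1] <= 25.0 or res.n_points == max(passing)
        # with the default 20-min cap the window edge is the last pair <= 20
        capped = detect_linear_phase(x, y, max_exposure=20.0)
        assert capped.window[1] == 18.0
        assert not capped.warning

    def test_needs_three_pairs(self):
        with pytest.raises(InsufficientDataError):
            detect_linear_phase([1.0, 2.0], [1.0, 2.0])

    def test_fallback_to_minimal_window_with_warning(self):
        rng = np.random.default_rng(0)
        x = np.linspace(1, 10, 8)
        y = rng.normal(0, 10, 8)  # no linear structure
        res = detect_linear_phase(x, y, max_exposure=None, r2_threshold=0.9999)
        if res.n_points == 2:
            assert res.warning

    def test_saturable_uptake_full_window_underestimates_early_slope(self):
        """Concave (saturating) uptake: full-window slope < early-window slope."""
        x = np.linspace(1, 60, 30)
        y = 50 * (1 - np.exp(-x / 20)) + 5  # concave in exposure time
        full = patlak_fit(x, y)
        early = patlak_fit(x, y, phase_window=(0.0, 15.0))
        assert full.ki < early.ki


class TestCompareKi:
    def test_self_comparison_is_null(self, default_means):
        from bbbkinetics.synthetic import ExperimentConfig, TransportParams, simulate_uptake

        cfg = ExperimentConfig(noise_cv=0.05, rng_seed=3)
        s = simulate_uptake(
            default_means,
            TransportParams(mode="linear", ki_true=0.2, vi_true=15.0),
            cfg,
        )
        fit = fit_series(s)
        res = compare_ki(fit, fit)
        assert res.estimate == 0.0
        assert res.p_value == 1.0

    def test_closed_form_t_statistic(self):
        """Slopes 1.0 +/- 0.1 vs 0.5 +/- 0.1 give t = 0.5/sqrt(0.02) = 3.54."""
        def fake_fit(ki, se, n=10):
            x = np.linspace(0, 9, n)
            from bbbkinetics.patlak import PatlakFit

            return PatlakFit(
                ki=ki, vi=0.0, ki_se=se, vi_se=0.0, r_squared=0.9,
                n_points=n, exposure_times=x, ratios=ki * x,
                phase_window=(0.0, 9.0),
            )

        res = compare_ki(fake_fit(1.0, 0.1), fake_fit(0.5, 0.1))
        assert res.t_stat == pytest.approx(0.5 / np.sqrt(0.02), rel=1e-9)
        assert res.t_stat == pytest.approx(3.54, abs=0.01)
        assert 0 < res.p_value < 0.05

    def test_antisymmetric_in_arguments(self):
        from bbbkinetics.patlak import PatlakFit

        def f(ki, se):
            x = np.linspace(0, 9, 10)
            return PatlakFit(ki, 0.0, se, 0.0, 0.9, 10, x, ki * x, (0.0, 9.0))

        a, b = f(1.0, 0.1), f(0.5, 0.2)
        r1, r2 = compare_ki(a, b), compare_ki(b, a)
        assert r1.estimate == -r2.estimate
        assert r1.p_value == r2.p_value

    def test_zero_se_conventions(self):
        from bbbkinetics.patlak import PatlakFit

        def f(ki):
            x = np.linspace(0, 9, 10)
            return PatlakFit(ki, 0.0, 0.0, 0.0, 1.0, 10, x, ki * x, (0.0, 9.0))

        equal = compare_ki(f(1.0), f(1.0))
        assert equal.p_value == 1.0 and equal.degenerate
        unequal = compare_ki(f(1.0), f(0.5))
        assert unequal.p_value == 0.0 and np.isinf(unequal.t_stat)

    def test_requires_three_points(self):
        fit2 = patlak_fit([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(InsufficientDataError):
            compare_ki(fit2, fit2)
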