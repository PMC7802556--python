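"""Unit and property tests for the three candidate kinetic laws."""

import numpy as np
import pytest
from scipy import optimize

from maillard_kinetics.kinetic_models import (
    FitWindow,
    KineticDomainError,
    KineticParams,
    ModelForm,
    NonPositiveConcentrationError,
    fit_kinetic,
    predict,
)

from conftest import make_series

ZERO = ModelForm.ZERO_ORDER
EXP = ModelForm.FIRST_ORDER_EXP
LOG = ModelForm.LOGARITHMIC


class TestPredict:
    @pytest.mark.parametrize(
        "form, c0, k, t, expected",
        [
            (ZERO, 0.0049, 0.0028, 0.0, 0.0049),            # intercept at t=0
            (EXP, 3.7, 0.0, 5.0, 3.7),                      # zero-rate identity
            (EXP, 2.0, 0.0, 0.5, 2.0),
            (ZERO, 54103.0, -352.65, 6.0, 51987.1),         # glucose decay endpoint
            (LOG, 1e-4, 2e-4, 1.0, 1e-4),                   # ln 1 = 0
        ],
    )
    def test_pointwise_evaluation(self, form, c0, k, t, expected):
        params = KineticParams(form, c0=c0, k=k)
        assert predict(params, [t])[0] == pytest.approx(expected, rel=1e-12)

    def test_output_length_matches_input(self):
        params = KineticParams(ZERO, 1.0, 2.0)
        assert predict(params, [0, 1, 2, 3]).shape == (4,)

    def test_logarithmic_rejects_nonpositive_times(self):
        params = KineticParams(LOG, 1.0, 1.0)
        with pytest.raises(KineticDomainError, match="0.0"):
            predict(params, [2.0, 0.0, 3.0])
        with pytest.raises(KineticDomainError):
            predict(params, [-1.0])

    def test_exponential_monotone_iff_positive_rate(self):
        t = np.linspace(0, 6, 13)
        up = predict(KineticParams(EXP, 0.5, 0.3), t)
        down = predict(KineticParams(EXP, 0.5, -0.3), t)
        assert np.all(np.diff(up) > 0)
        assert np.all(np.diff(down) < 0)

    def test_exponential_requires_positive_c0(self):
        with pytest.raises(ValueError):
            KineticParams(EXP, c0=-1.0, k=0.1)


class TestFitKinetic:
    @pytest.mark.parametrize(
        "form, c0, k, window",
        [
            (ZERO, 0.0049, 0.0028, FitWindow(1, 6)),
            (ZERO, 54103.0, -352.65, FitWindow(0, 6)),
            (EXP, 8e-6, 0.3968, FitWindow(1, 6)),
            (EXP, 53617.0, -0.034, FitWindow(0, 6)),
            (LOG, 1e-4, 2e-4, FitWindow(1, 6)),
            (LOG, -3e-5, 3e-5, FitWindow(3, 6)),
        ],
    )
    def test_exact_recovery_from_noiseless_data(self, form, c0, k, window):
        """Transform-space OLS recovers generating parameters exactly."""
        times = np.arange(window.t_start, window.t_end + 1)
        params = KineticParams(form, c0, k)
        series = make_series(times, predict(params, times))
        fit = fit_kinetic(series, form, window)
        assert fit.fittable
        assert fit.params.k == pytest.approx(k, rel=1e-9, abs=1e-15)
        assert fit.params.c0 == pytest.approx(c0, rel=1e-9, abs=1e-15)
        assert fit.gof.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_constant_series_gives_zero_slope(self):
        series = make_series([1, 2, 3, 4, 5, 6], [2.5] * 6)
        fit = fit_kinetic(series, ZERO, FitWindow(1, 6))
        assert fit.params.k == pytest.approx(0.0, abs=1e-12)
        assert fit.params.c0 == pytest.approx(2.5)
        assert np.isnan(fit.gof.r_squared)  # R^2 undefined on constant data

    def test_window_restriction_ignores_t0(self):
        """A t=0 observation must not influence a (1-6) fit."""
        params = KineticParams(ZERO, 0.01, 0.002)
        t_in = np.arange(1, 7)
        with_t0 = make_series(np.arange(0, 7), np.r_[99.0, predict(params, t_in)])
        without = make_series(t_in, predict(params, t_in))
        f1 = fit_kinetic(with_t0, ZERO, FitWindow(1, 6))
        f2 = fit_kinetic(without, ZERO, FitWindow(1, 6))
        assert f1.params == f2.params
        assert f1.window == f2.window
        assert f1.n_points == f2.n_points

    def test_censored_points_are_dropped(self):
        params = KineticParams(ZERO, 1.0, 0.5)
        t = np.arange(1, 7)
        c = predict(params, t).copy()
        c[0] = 123.0  # wildly wrong, but censored
        series = make_series(t, c, censored=[True, False, False, False, False, False])
        fit = fit_kinetic(series, ZERO, FitWindow(1, 6))
        assert fit.params.k == pytest.approx(0.5, rel=1e-12)
        assert fit.window == FitWindow(2, 6)  # effective span of used points

    def test_too_few_points_is_unfittable_not_an_error(self):
        series = make_series([1, 2], [1.0, 2.0])
        fit = fit_kinetic(series, ZERO, FitWindow(1, 6))
        assert not fit.fittable
        assert fit.n_points == 2
        assert "3 usable points" in fit.reason
        assert fit.gof is None

    def test_empty_window_is_unfittable_with_reason(self):
        series = make_series([1, 2, 3], [1.0, 2.0, 3.0])
        fit = fit_kinetic(series, ZERO, FitWindow(4, 6))
        assert not fit.fittable
        assert "excludes all" in fit.reason

    def test_exponential_rejects_nonpositive_concentrations(self):
        series = make_series([1, 2, 3, 4], [1.0, 0.0, 2.0, 3.0])
        with pytest.raises(NonPositiveConcentrationError, match="2.0, 0.0"):
            fit_kinetic(series, EXP, FitWindow(1, 6))

    def test_logarithmic_rejects_window_reaching_zero(self):
        series = make_series([0, 1, 2, 3], [1.0, 2.0, 3.0, 4.0])
        with pytest.raises(KineticDomainError):
            fit_kinetic(series, LOG, FitWindow(0, 6))

    def test_replicate_means_aggregation_equals_fit_on_means(self):
        rng = np.random.default_rng(7)
        t = np.arange(1, 7)
        base = predict(KineticParams(ZERO, 1.0, 0.5), t)
        reps = [base * (1 + rng.normal(0, 0.05, t.size)) for _ in range(3)]
        import maillard_kinetics.panel as panel_mod

        series = panel_mod.TimeSeries(
            system="glucose_only",
            compound="x",
            temperature=90.0,
            time_h=np.tile(t, 3),
            replicate=np.repeat([0, 1, 2], t.size),
            concentration=np.concatenate(reps),
            censored=np.zeros(3 * t.size, bool),
        )
        mean_series = make_series(t, np.mean(reps, axis=0))
        f_means = fit_kinetic(series, ZERO, FitWindow(1, 6), aggregation="replicate_means")
        f_ref = fit_kinetic(mean_series, ZERO, FitWindow(1, 6))
        assert f_means.params.k == pytest.approx(f_ref.params.k, rel=1e-12)
        f_pooled = fit_kinetic(series, ZERO, FitWindow(1, 6), aggregation="pooled")
        assert f_pooled.n_points == 18

    def test_transformed_r2_option(self):
        rng = np.random.default_rng(3)
        t = np.arange(1, 7)
        c = predict(KineticParams(EXP, 1.0, 0.5), t) * (1 + rng.normal(0, 0.1, t.size))
        series = make_series(t, np.abs(c))
        orig = fit_kinetic(series, EXP, FitWindow(1, 6), r2_space="original")
        trans = fit_kinetic(series, EXP, FitWindow(1, 6), r2_space="transformed")
        assert orig.params == trans.params  # only the reported R^2 differs
        assert orig.gof.r_squared != trans.gof.r_squared


class TestOracleEquivalence:
    """Transform-space OLS must agree with direct numerical SSE minimisation."""

    @pytest.mark.parametrize("form", [ZERO, EXP, LOG])
    def test_matches_numerical_minimiser(self, form):
        rng = np.random.default_rng(42)
        t = np.arange(1, 7, dtype=float)
        truth = KineticParams(form, 0.8, 0.25)
        c = np.abs(predict(truth, t) * (1 + rng.normal(0, 0.08, t.size)))
        series = make_series(t, c, compound="x")
        fit = fit_kinetic(series, form, FitWindow(1, 6))

        if form is ZERO:
            x, y = t, c
        elif form is EXP:
            x, y = t, np.log(c)
        else:
            x, y = np.log(t), c

        def sse(theta):
            a, b = theta
            return np.sum((y - (a + b * x)) ** 2)

        # independent route: coarse grid then simplex refinement
        grid_a = np.linspace(y.min() - 1, y.max() + 1, 41)
        grid_b = np.linspace(-2, 2, 41)
        best = min(
            ((a, b) for a in grid_a for b in grid_b), key=lambda th: sse(th)
        )
        res = optimize.minimize(sse, best, method="Nelder-Mead",
                                options={"xatol": 1e-12, "fatol": 1e-16})
        a_hat, b_hat = res.x
        assert fit.params.k == pytest.approx(b_hat, abs=1e-5)
        intercept = np.log(fit.params.c0) if form is EXP else fit.params.c0
        assert intercept == pytest.approx(a_hat, abs=1e-5)
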