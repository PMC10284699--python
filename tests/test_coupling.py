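import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from watercarbon.containers import AnnualSeries, DegenerateInputError
from watercarbon.coupling import (
    bootstrap_stat,
    change_significance,
    moving_window,
    ols_sensitivity,
    partial_corr,
    pearson_corr,
    ridge_sensitivity,
    window_analysis,
    window_corr_bootstrap,
)


def series(vals, start=2000):
    vals = np.asarray(vals, dtype=float)
    return AnnualSeries(np.arange(start, start + vals.size), vals)


class TestPearson:
    def test_perfect_linear_relations(self):
        x = series([1.0, 2.0, 3.0, 5.0])
        r_pos, p_pos = pearson_corr(x, series(2.0 * x.values + 1.0))
        r_neg, _ = pearson_corr(x, series(-x.values))
        assert r_pos == pytest.approx(1.0)
        assert r_neg == pytest.approx(-1.0)
        assert p_pos < 1e-6

    def test_hand_computed_value(self):
        # product-moment formula evaluated by hand for (1,2,3,4),(1,2,2,4)
        r, _ = pearson_corr(series([1, 2, 3, 4]), series([1, 2, 2, 4]))
        assert r == pytest.approx(4.5 / np.sqrt(5.0 * 4.75), abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateInputError):
            pearson_corr(series([1.0, 1.0, 1.0]), series([1.0, 2.0, 3.0]))

    def test_respects_validity_masks(self):
        x = series([1.0, 2.0, 3.0, 4.0, 100.0])
        y = series([1.1, 1.9, 3.2, 3.8, -50.0])
        x.valid[4] = False
        r_masked, _ = pearson_corr(x, y)
        r_clean, _ = pearson_corr(series(x.values[:4]), series(y.values[:4]))
        assert r_masked == pytest.approx(r_clean)

    @given(
        st.lists(st.floats(-100, 100), min_size=5, max_size=30),
        st.floats(0.1, 10),
        st.floats(-5, 5),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetric_and_scale_invariant(self, vals, scale, shift):
        x = series(vals)
        rng = np.random.default_rng(7)
        y = series(np.asarray(vals) + rng.standard_normal(len(vals)))
        try:
            r_xy, _ = pearson_corr(x, y)
            r_yx, _ = pearson_corr(y, x)
            r_scaled, _ = pearson_corr(series(scale * x.values + shift), y)
        except DegenerateInputError:
            return
        assert r_xy == pytest.approx(r_yx, abs=1e-12)
        assert r_xy == pytest.approx(r_scaled, abs=1e-9)


class TestPartialCorr:
    def test_independent_control_leaves_correlation(self):
        # z exactly uncorrelated with both x and y by construction
        x = series([1.0, 2.0, 2.0, 1.0])
        y = series([0.0, 1.0, 3.0, 2.0])
        z = series([1.0, -1.0, 1.0, -1.0])
        r_xy, _ = pearson_corr(x, y)
        r_partial, _ = partial_corr(x, y, z)
        assert r_partial == pytest.approx(r_xy, abs=1e-12)

    def test_control_collinear_with_y_raises(self):
        x = series([1.0, 2.0, 4.0, 3.0])
        y = series([5.0, 1.0, 2.0, 4.0])
        with pytest.raises(DegenerateInputError):
            partial_corr(x, y, y.copy())

    def test_nearly_explained_variable_gives_near_zero(self):
        # y = z + tiny noise: the partial correlation reduces to the
        # correlation of x with that noise, O(1/sqrt(n)) around zero
        rng = np.random.default_rng(3)
        n = 2000
        z = series(rng.standard_normal(n))
        y = series(z.values + 1e-6 * rng.standard_normal(n))
        x = series(rng.standard_normal(n))
        r, _ = partial_corr(x, y, z)
        assert abs(r) < 5.0 / np.sqrt(n)

    def test_formula_equals_residual_regression(self):
        # oracle: correlate the OLS residuals of x|z and y|z
        rng = np.random.default_rng(11)
        for _ in range(20):
            xv, yv, zv = rng.standard_normal((3, 20))
            x, y, z = series(xv), series(yv), series(zv)
            r_formula, _ = partial_corr(x, y, z)
            rx = xv - np.polyval(np.polyfit(zv, xv, 1), zv)
            ry = yv - np.polyval(np.polyfit(zv, yv, 1), zv)
            r_resid = np.corrcoef(rx, ry)[0, 1]
            assert r_formula == pytest.approx(r_resid, abs=1e-12)


class TestBootstrap:
    def test_constant_series_mean_replicates_constant(self):
        s = series(np.full(10, 4.2))
        res = bootstrap_stat(lambda v: v.mean(), [s], n_reps=200, seed=0)
        np.testing.assert_allclose(res.replicates, 4.2)
        assert res.ci == (pytest.approx(4.2), pytest.approx(4.2))

    def test_perfectly_correlated_pair_replicates_are_one(self):
        x = series(np.arange(10.0))
        res = bootstrap_stat(
            lambda a, b: np.corrcoef(a, b)[0, 1] if np.ptp(a) > 0 else np.nan,
            [x, x.copy()], n_reps=300, seed=1,
        )
        np.testing.assert_allclose(res.replicates, 1.0)

    def test_bootstrap_se_of_mean_matches_analytic(self):
        rng = np.random.default_rng(5)
        vals = rng.standard_normal(10) * 3.0
        s = series(vals)
        res = bootstrap_stat(lambda v: v.mean(), [s], n_reps=5000, seed=2)
        analytic = vals.std(ddof=0) / np.sqrt(vals.size)
        assert res.replicates.std() == pytest.approx(analytic, rel=0.15)

    def test_reproducible_with_fixed_seed(self):
        s = series(np.arange(12.0))
        a = bootstrap_stat(lambda v: v.mean(), [s], n_reps=100, seed=9)
        b = bootstrap_stat(lambda v: v.mean(), [s], n_reps=100, seed=9)
        np.testing.assert_array_equal(a.replicates, b.replicates)

    def test_redraw_cap_raises_when_always_degenerate(self):
        s = series(np.arange(5.0))
        with pytest.raises(DegenerateInputError):
            bootstrap_stat(lambda v: np.nan, [s], n_reps=10, seed=0)

    def test_ci_coverage_gaussian(self):
        # nominal 95% percentile CI for the mean, n=30: empirical coverage
        # within 3 percentage points over 300 simulations
        rng = np.random.default_rng(21)
        hits = 0
        n_sim = 300
        for i in range(n_sim):
            vals = rng.standard_normal(30)
            res = bootstrap_stat(
                lambda v: v.mean(), [series(vals)], n_reps=600, seed=i
            )
            hits += res.covers(0.0)
        assert hits / n_sim == pytest.approx(0.95, abs=0.03)


class TestChangeSignificance:
    def test_identical_results_give_zero_delta_p_one(self):
        s = series(np.arange(10.0) + np.sin(np.arange(10)))
        a = bootstrap_stat(lambda v: v.mean(), [s], n_reps=500, seed=3)
        delta, p = change_significance(a, a)
        assert delta == 0.0
        assert p == 1.0

    def test_disjoint_supports_give_tiny_p(self):
        a = bootstrap_stat(lambda v: v.mean(), [series(np.arange(10.0))],
                           n_reps=500, seed=4)
        b = bootstrap_stat(lambda v: v.mean(), [series(np.arange(10.0) + 100)],
                           n_reps=500, seed=5)
        delta, p = change_significance(a, b)
        assert delta == pytest.approx(100.0)
        assert p <= 2.0 / 500

    def test_mismatched_statistics_rejected(self):
        s = series(np.arange(10.0))
        a = bootstrap_stat(lambda v: v.mean(), [s], n_reps=50, seed=0,
                           statistic_name="mean")
        b = bootstrap_stat(lambda v: v.std(), [s], n_reps=50, seed=0,
                           statistic_name="std")
        with pytest.raises(ValueError):
            change_significance(a, b)


class TestSensitivities:
    def test_exact_univariate_slope(self):
        x = series([0.0, 1.0, 2.0, 4.0, 7.0])
        est = ols_sensitivity(series(-1.2 * x.values), x, n_reps=50)
        assert est.gamma == pytest.approx(-1.2, abs=1e-12)
        assert est.model_kind == "univariate_ols"
        assert est.regularization == 0.0

    def test_standardized_noise_free_slope_is_one(self):
        rng = np.random.default_rng(8)
        xv = rng.standard_normal(30)
        xv = (xv - xv.mean()) / xv.std()
        est = ols_sensitivity(series(xv), series(xv), n_reps=50)
        assert est.gamma == pytest.approx(1.0, abs=1e-12)

    def test_ridge_zero_penalty_equals_ols_oracle(self):
        # independent oracle: bivariate OLS via numpy lstsq
        rng = np.random.default_rng(12)
        x1v, x2v = rng.standard_normal((2, 40))
        yv = -1.0 * x1v + 2.0 * x2v + 0.3 * rng.standard_normal(40)
        g1, g2 = ridge_sensitivity(
            series(yv), series(x1v), series(x2v), n_reps=10, forced_lambda=0.0
        )
        X = np.column_stack([np.ones(40), x1v, x2v])
        beta = np.linalg.lstsq(X, yv, rcond=None)[0]
        assert g1.gamma == pytest.approx(beta[1], abs=1e-10)
        assert g2.gamma == pytest.approx(beta[2], abs=1e-10)

    def test_fixed_penalty_matches_sklearn(self):
        from sklearn.linear_model import Ridge

        rng = np.random.default_rng(13)
        x1v, x2v = rng.standard_normal((2, 35))
        yv = 0.5 * x1v - 1.5 * x2v + rng.standard_normal(35)
        lam = 2.7
        g1, g2 = ridge_sensitivity(
            series(yv), series(x1v), series(x2v), n_reps=10, forced_lambda=lam
        )
        X = np.column_stack([x1v, x2v])
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        model = Ridge(alpha=lam, fit_intercept=True).fit(Xs, yv)
        np.testing.assert_allclose(
            [g1.gamma, g2.gamma], model.coef_ / X.std(0, ddof=1), atol=1e-10
        )

    def test_monotone_shrinkage_with_penalty(self):
        rng = np.random.default_rng(14)
        x1v, x2v = rng.standard_normal((2, 30))
        yv = x1v + x2v + 0.1 * rng.standard_normal(30)
        norms = []
        for lam in [0.0, 1.0, 10.0, 100.0]:
            g1, g2 = ridge_sensitivity(
                series(yv), series(x1v), series(x2v), n_reps=10, forced_lambda=lam
            )
            norms.append(np.hypot(g1.gamma, g2.gamma))
        assert np.all(np.diff(norms) < 0)

    def test_collinear_predictors_ols_raises_ridge_warns(self):
        xv = np.arange(20.0)
        y = series(xv + 1.0)
        with pytest.raises(DegenerateInputError):
            ridge_sensitivity(y, series(xv), series(2 * xv), n_reps=10, mode="ols")
        with pytest.warns(UserWarning):
            ridge_sensitivity(
                y, series(xv), series(2 * xv), n_reps=10, forced_lambda=1.0
            )


class TestWindows:
    def _bundle(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        w = series(rng.standard_normal(n), start=1960)
        t = series(rng.standard_normal(n), start=1960)
        c = series(-w.values + t.values + 0.5 * rng.standard_normal(n), start=1960)
        return {"cgr": c, "water": w, "temp": t}

    def test_full_span_window_equals_full_period(self):
        from watercarbon.preprocess import detrend_linear

        b = self._bundle()
        df = window_analysis(b, [(1960, 1999)], n_reps=50, seed=0)
        r_full, _ = pearson_corr(
            detrend_linear(b["water"]), detrend_linear(b["cgr"])
        )
        row = df[df.statistic == "R_water_cgr"].iloc[0]
        assert row.estimate == pytest.approx(r_full, abs=1e-12)

    def test_window_outside_span_rejected(self):
        with pytest.raises(ValueError):
            window_analysis(self._bundle(), [(1900, 1910)], n_reps=10)

    def test_shared_boundary_year_allowed(self):
        df = window_analysis(
            self._bundle(), [(1960, 1980), (1980, 1999)], n_reps=20, seed=0
        )
        assert set(zip(df.window_start, df.window_end)) == {(1960, 1980), (1980, 1999)}

    def test_moving_window_width_equal_span_single_value(self):
        from watercarbon.preprocess import detrend_linear

        b = self._bundle()
        mw = moving_window(b["water"], b["cgr"], width=40)
        assert mw.values.size == 1
        r_full, _ = pearson_corr(
            detrend_linear(b["water"]), detrend_linear(b["cgr"])
        )
        assert mw.values[0] == pytest.approx(r_full, abs=1e-12)

    def test_moving_window_too_narrow_rejected(self):
        b = self._bundle()
        with pytest.raises(ValueError):
            moving_window(b["water"], b["cgr"], width=4)

    def test_window_bootstrap_redetrends_by_default(self):
        # a strong shared trend inflates the raw correlation; re-detrending
        # within the window must remove it
        n = 30
        rng = np.random.default_rng(15)
        years = np.arange(1960, 1960 + n)
        trend = 0.5 * (years - years[0])
        x = AnnualSeries(years, trend + rng.standard_normal(n))
        y = AnnualSeries(years, trend + rng.standard_normal(n))
        res = window_corr_bootstrap(x, y, (1960, 1989), n_reps=50, seed=0)
        raw = np.corrcoef(x.values, y.values)[0, 1]
        assert raw > 0.9
        assert abs(res.point_estimate) < 0.5
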