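"""Trend-model tests: VIF closed forms, OLS against statsmodels, Matérn
correlation values, spatial mixed-model identities, AIC selection rules,
Moran's I behaviour and marginal-effect predictions."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from phylotrends._util import pairwise_haversine
from phylotrends.trends import (
    TrendDesign,
    aic_select,
    fit_lm,
    fit_spatial_mixed,
    marginal_effects,
    matern_corr,
    model_menu,
    morans_correlogram,
    prepare_trend_frame,
    run_regions,
    vif,
)


def make_design(frame):
    prepared, _ = prepare_trend_frame(frame)
    return TrendDesign(prepared)


class TestVif:
    def _design_from_columns(self, **cols):
        n = len(next(iter(cols.values())))
        df = pd.DataFrame(cols)
        df["z"] = np.random.default_rng(0).normal(size=n)
        df["lat_2dp"] = np.linspace(-50, 50, n).round(2)
        df["lon_2dp"] = np.linspace(-150, 150, n).round(2)
        df["year"] = 2010
        df["degenerate"] = False
        return make_design(df)

    def test_orthogonal_predictors_have_unit_vif(self):
        x = np.tile([1.0, -1.0], 50)
        y = np.repeat([1.0, -1.0], 50)
        design = self._design_from_columns(temperature=x, precipitation=y)
        out = vif(design, ["temperature", "precipitation"])
        assert out["temperature"] == pytest.approx(1.0)
        assert out["precipitation"] == pytest.approx(1.0)

    def test_correlated_pair_matches_closed_form(self):
        # sample correlation exactly 0.8 -> VIF = 1/(1-0.64) = 2.7778
        n = 100
        u = np.sin(np.arange(n))
        u = (u - u.mean()) / u.std()
        v = np.cos(np.arange(n))
        v = (v - v.mean()) / v.std()
        v = v - (u @ v / (u @ u)) * u
        v /= v.std()
        x2 = 0.8 * u + np.sqrt(1 - 0.64) * v
        design = self._design_from_columns(temperature=u, precipitation=x2)
        out = vif(design, ["temperature", "precipitation"])
        assert out["temperature"] == pytest.approx(1 / (1 - 0.64), rel=1e-6)

    def test_duplicated_column_reports_infinite(self):
        x = np.linspace(0, 1, 60)
        design = self._design_from_columns(temperature=x, precipitation=x)
        with pytest.warns(UserWarning, match="collinear"):
            out = vif(design, ["temperature", "precipitation"])
        assert np.isinf(out["temperature"]) and np.isinf(out["precipitation"])


class TestFitLm:
    def test_noise_free_data_recovered_exactly(self, trend_frame):
        frame, _ = prepare_trend_frame(trend_frame)
        frame["z"] = 1.0 + 0.5 * frame["abs_latitude"] - 2.0 * frame["year_s"]
        design = TrendDesign(frame)
        fit = fit_lm(design, ["abs_latitude", "year_s"])
        assert fit.params["(Intercept)"] == pytest.approx(1.0, abs=1e-9)
        assert fit.params["abs_latitude"] == pytest.approx(0.5, abs=1e-9)
        assert fit.params["year_s"] == pytest.approx(-2.0, abs=1e-9)

    def test_matches_statsmodels_ols(self, trend_frame):
        design = make_design(trend_frame)
        terms = ["abs_latitude", "year_s", "hemisphere", "abs_latitude:year_s"]
        fit = fit_lm(design, terms)
        X, names, _ = design.matrix(terms)
        ref = sm.OLS(design.y, X).fit()
        assert np.allclose(fit.params.values, ref.params, rtol=1e-10)
        assert np.allclose(fit.bse.values, ref.bse, rtol=1e-10)
        assert fit.loglik == pytest.approx(ref.llf)
        # AIC counts the variance parameter in k
        assert fit.aic == pytest.approx(2 * (X.shape[1] + 1) - 2 * ref.llf)

    def test_intercept_only_recovers_mean(self, trend_frame):
        frame, _ = prepare_trend_frame(trend_frame)
        frame["z"] = 5.0 + np.zeros(len(frame))
        fit = fit_lm(TrendDesign(frame), [])
        assert fit.params["(Intercept)"] == pytest.approx(5.0)

    def test_rank_deficiency_drops_aliased_with_warning(self, trend_frame):
        frame, _ = prepare_trend_frame(trend_frame)
        frame["temperature"] = 2.0 * frame["abs_latitude"]
        design = TrendDesign(frame)
        with pytest.warns(UserWarning, match="aliased"):
            fit = fit_lm(design, ["abs_latitude", "temperature"])
        assert len(fit.dropped_columns) == 1


class TestMaternCorr:
    def test_distance_zero_is_one(self):
        assert matern_corr(0.0, 100.0, 0.5) == pytest.approx(1.0)
        assert matern_corr(0.0, 100.0, 1.5) == pytest.approx(1.0)

    def test_exponential_closed_form(self):
        d = np.linspace(0, 5000, 101)
        assert np.allclose(matern_corr(d, 750.0, 0.5), np.exp(-d / 750.0), atol=1e-12)

    def test_nu_three_halves_at_rho(self):
        # direct evaluation of the closed form (1 + sqrt(3)) * exp(-sqrt(3))
        val = matern_corr(750.0, 750.0, 1.5)
        assert val == pytest.approx((1 + np.sqrt(3)) * np.exp(-np.sqrt(3)), abs=1e-12)
        assert val == pytest.approx(0.4833577, abs=1e-6)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            matern_corr(1.0, -1.0, 0.5)
        with pytest.raises(ValueError):
            matern_corr(1.0, 1.0, 2.5)


class TestSpatialMixed:
    def test_pinned_variances_reproduce_ols_exactly(self, trend_frame):
        design = make_design(trend_frame)
        terms = ["abs_latitude", "year_s"]
        ols = fit_lm(design, terms)
        pinned = fit_spatial_mixed(design, terms, fix_zero=("spatial", "group"))
        assert np.allclose(pinned.params.values, ols.params.values, rtol=1e-6)
        assert pinned.loglik == pytest.approx(ols.loglik, rel=1e-9)

    def test_free_fit_on_independent_data_stays_near_ols(self, trend_frame):
        design = make_design(trend_frame)
        terms = ["abs_latitude", "year_s"]
        ols = fit_lm(design, terms)
        free = fit_spatial_mixed(design, terms)
        assert free.converged
        diff_in_se = np.abs(free.params.values - ols.params.values) / ols.bse.values
        assert np.all(diff_in_se < 2.0)
        assert free.loglik >= ols.loglik - 1e-6  # nested-model likelihood ordering

    def test_duplicated_rows_favor_group_variance(self, trend_frame):
        frame, _ = prepare_trend_frame(trend_frame)
        rng = np.random.default_rng(2)
        frame = frame.iloc[:40].copy()
        frame["z"] = 0.5 + rng.normal(0, 1, len(frame))
        doubled = pd.concat([frame, frame], ignore_index=True)
        doubled.attrs = dict(frame.attrs)
        design = TrendDesign(doubled)
        ols = fit_lm(design, ["abs_latitude"])
        mixed = fit_spatial_mixed(design, ["abs_latitude"], fix_zero=("spatial",))
        assert mixed.matern.sigma2_group > 0
        assert mixed.loglik > ols.loglik

    def test_recovers_planted_spatial_structure(self, trend_frame):
        frame, _ = prepare_trend_frame(trend_frame)
        rng = np.random.default_rng(6)
        D = pairwise_haversine(frame["lat_2dp"], frame["lon_2dp"])
        K = matern_corr(D, 2000.0, 1.5)
        L = np.linalg.cholesky(K + 1e-8 * np.eye(len(frame)))
        frame["z"] = 1.0 + 0.03 * frame["abs_latitude"] + 1.5 * (L @ rng.normal(0, 1, len(frame))) + rng.normal(0, 0.3, len(frame))
        design = TrendDesign(frame)
        fit = fit_spatial_mixed(design, ["abs_latitude"])
        assert fit.converged
        assert fit.matern.sigma2_spatial > fit.matern.sigma2_resid
        lo = fit.params["abs_latitude"] - 2.5 * fit.bse["abs_latitude"]
        hi = fit.params["abs_latitude"] + 2.5 * fit.bse["abs_latitude"]
        assert lo < 0.03 < hi


class TestAicSelect:
    def test_single_candidate_selected(self, trend_frame):
        design = make_design(trend_frame)
        fit = fit_lm(design, ["abs_latitude"])
        table, selected = aic_select([fit])
        assert selected is fit and len(table) == 1

    def test_tie_within_two_units_prefers_fewer_parameters(self, trend_frame):
        design = make_design(trend_frame)
        small = fit_lm(design, ["abs_latitude", "year_s"])
        big = fit_lm(design, ["abs_latitude", "year_s", "hemisphere"])
        if abs(small.aic - big.aic) <= 2.0:
            _, selected = aic_select([big, small])
            assert selected is small

    def test_spurious_terms_rejected_by_aic_majority(self):
        # intercept-only truth vs 5 spurious predictors, many replicates
        wins = 0
        reps = 40
        for r in range(reps):
            rng = np.random.default_rng(300 + r)
            n = 400
            df = pd.DataFrame(
                {
                    "lat_2dp": rng.uniform(-60, 60, n).round(2),
                    "lon_2dp": rng.uniform(-170, 170, n).round(2),
                    "year": rng.integers(1990, 2020, n),
                    "temperature": rng.normal(size=n),
                    "precipitation": rng.normal(size=n),
                    "elevation": rng.normal(size=n),
                    "degenerate": False,
                }
            )
            df["z"] = 2.0 + rng.normal(0, 1, n)
            frame, _ = prepare_trend_frame(df)
            design = TrendDesign(frame)
            full = fit_lm(
                design,
                ["abs_latitude", "year_s", "temperature", "precipitation", "elevation"],
            )
            reduced = fit_lm(design, [])
            _, selected = aic_select([full, reduced])
            wins += selected is reduced
        assert wins > reps / 2

    def test_mismatched_rows_error(self, trend_frame):
        design = make_design(trend_frame)
        other = make_design(trend_frame.iloc[:50])
        with pytest.raises(ValueError, match="identical response"):
            aic_select([fit_lm(design, []), fit_lm(other, [])])

    def test_nested_loglik_ordering(self, trend_frame):
        design = make_design(trend_frame)
        small = fit_lm(design, ["abs_latitude"])
        big = fit_lm(design, ["abs_latitude", "year_s", "abs_latitude:year_s"])
        assert big.loglik >= small.loglik - 1e-6


class TestMoransCorrelogram:
    def _coords(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return np.column_stack([rng.uniform(-40, 40, n), rng.uniform(-120, 120, n)])

    def test_smooth_field_detected_in_first_bin(self):
        coords = self._coords(80, seed=1)
        smooth = np.sin(np.radians(coords[:, 0]) * 3) + np.cos(np.radians(coords[:, 1]) * 2)
        res = morans_correlogram(smooth, coords, [0, 1500, 4000, 10000], n_perm=199, seed=2)
        assert res.morans_i[0] > 0
        assert res.p_perm[0] <= 0.01

    def test_constant_residuals_report_missing(self):
        coords = self._coords(30)
        res = morans_correlogram(np.ones(30), coords, [0, 3000, 10000], n_perm=99, seed=0)
        assert np.isnan(res.morans_i).all()

    def test_empty_bin_reported_missing(self):
        coords = self._coords(30)
        res = morans_correlogram(
            np.random.default_rng(1).normal(size=30),
            coords,
            [0, 1e-6, 10000, 20000],
            n_perm=99,
            seed=0,
        )
        assert np.isnan(res.morans_i[0])
        assert np.isnan(res.p_perm[0])
        assert res.n_pairs[0] == 0

    def test_scaling_residuals_changes_nothing(self):
        coords = self._coords(50, seed=3)
        r = np.random.default_rng(4).normal(size=50)
        a = morans_correlogram(r, coords, [0, 3000, 8000], n_perm=199, seed=9)
        b = morans_correlogram(1000.0 * r, coords, [0, 3000, 8000], n_perm=199, seed=9)
        assert np.allclose(a.morans_i, b.morans_i, equal_nan=True)
        assert np.allclose(a.p_perm, b.p_perm, equal_nan=True)

    def test_argument_validation(self):
        coords = self._coords(10)
        with pytest.raises(ValueError):
            morans_correlogram(np.zeros(10), coords, [0, 1000], n_perm=99, seed=0)
        with pytest.raises(ValueError):
            morans_correlogram(np.zeros(10), coords, [0, 1000, 2000], n_perm=10, seed=0)


class TestMarginalEffects:
    def test_ols_prediction_matches_fitted_value(self, trend_frame):
        design = make_design(trend_frame)
        terms = ["abs_latitude", "year_s"]
        fit = fit_lm(design, terms)
        row = design.frame.iloc[0]
        out = marginal_effects(fit, [row["abs_latitude"]], [row["year"]])
        X, _, _ = design.matrix(terms)
        fitted = (X @ fit.params.values)[0]
        assert out["predicted"].iloc[0] == pytest.approx(fitted)

    def test_positive_interaction_steepens_high_latitude_year_slope(self, trend_frame):
        frame, _ = prepare_trend_frame(trend_frame)
        frame["z"] = 0.1 + 0.02 * frame["abs_latitude"] * frame["year_s"]
        design = TrendDesign(frame)
        fit = fit_lm(design, ["abs_latitude", "year_s", "abs_latitude:year_s"])
        years = [2005, 2015]
        out = marginal_effects(fit, [0.0, 60.0], years)
        slope_at = lambda lat: np.diff(
            out[out["abs_latitude"] == lat].sort_values("year")["predicted"].values
        )[0]
        assert slope_at(60.0) > slope_at(0.0)

    def test_constant_response_gives_flat_grid(self, trend_frame):
        frame, _ = prepare_trend_frame(trend_frame)
        frame["z"] = 2.5
        fit = fit_lm(TrendDesign(frame), ["abs_latitude", "year_s"])
        out = marginal_effects(fit, [0, 30, 60], [2005, 2010, 2015])
        assert np.allclose(out["predicted"], 2.5, atol=1e-9)

    def test_extrapolation_flagged(self, trend_frame):
        design = make_design(trend_frame)
        fit = fit_lm(design, ["abs_latitude", "year_s"])
        out = marginal_effects(fit, [89.0], [2010])
        assert out["extrapolated"].all()


class TestRunRegions:
    def test_single_region_matches_global_fit(self, trend_frame):
        frame, _ = prepare_trend_frame(trend_frame)
        frame["region"] = "Europe"
        menu = [["abs_latitude", "year_s"], ["abs_latitude"]]
        results, skipped = run_regions(frame, menu, fitter="ols", min_rows=30)
        global_fit = aic_select(
            [fit_lm(TrendDesign(frame), m) for m in menu]
        )[1]
        assert not skipped
        regional = results["Europe"]["selected"]
        assert np.allclose(regional.params.values, global_fit.params.values)

    def test_small_region_skipped_with_reason(self, trend_frame):
        frame, _ = prepare_trend_frame(trend_frame)
        frame["region"] = ["Europe"] * 10 + ["Asia"] * (len(frame) - 10)
        results, skipped = run_regions(frame, [["abs_latitude"]], min_rows=30)
        assert "Europe" in skipped and "only 10 rows" in skipped["Europe"]
        assert "Asia" in results


def test_model_menu_contains_full_and_minimal():
    menu = model_menu(include_env=True)
    assert any("land_cover" in m for m in menu)
    assert ["abs_latitude", "year_s"] in menu
    assert any("abs_latitude:year_s" in m for m in menu)
    plain = model_menu(include_env=False)
    assert all("temperature" not in m for m in plain)
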