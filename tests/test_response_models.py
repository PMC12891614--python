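"""Tests for design building, logistic fitting (fixed and mixed), AIC
selection, accuracy, response curves and variogram diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from reefstress.response_models import (
    DesignInfo,
    FittedResponseModel,
    ModelSpec,
    SeparationError,
    analysis_table,
    build_design,
    candidate_models,
    design_matrix_for,
    fit_logistic,
    fit_logistic_mixed,
    fit_model,
    prediction_accuracy,
    residual_variogram,
    residuals,
    response_curve,
    select_by_aic,
)

# frozen R oracle fits (lme4::glmer / stats::glm) on tests/data/synthetic_glmm_fixture.csv
LME4_LAPLACE = {
    "beta": np.array([-1.51614939, 0.31971882]),
    "se": np.array([0.22341974, 0.02871523]),
    "sigma": 0.71919348,
    "loglik": -422.140684,
    "aic": 850.281368,
}
LME4_AGQ9 = {
    "beta": np.array([-1.51559992, 0.31966642]),
    "sigma": 0.72273472,
    "loglik": -422.042065,
}
GLM_FIXED = {"beta": np.array([-1.3362623229, 0.2833187048]), "loglik": -437.52219598}


def obs_frame(dhw, y, basin="AP", year="2014-15", station=None):
    n = len(dhw)
    return pd.DataFrame(
        {
            "dhw": dhw,
            "basin": np.broadcast_to(np.asarray(basin, dtype=object), n),
            "bleaching_year": np.broadcast_to(np.asarray(year, dtype=object), n),
            "y": y,
            "station_id": station if station is not None else np.zeros(n, dtype=int),
            "depth_m": np.nan,
        }
    )


class TestModelSpec:
    def test_dhw_always_included(self):
        assert "dhw" in ModelSpec("moderate_bleach", frozenset()).terms

    def test_hierarchy_enforced(self):
        with pytest.raises(ValueError):
            ModelSpec("moderate_bleach", frozenset({"basin:year"}))
        with pytest.raises(ValueError):
            ModelSpec("moderate_bleach", frozenset({"dhw:basin:year", "dhw:basin"}))

    def test_constrained_three_way_without_main_effects_allowed(self):
        spec = ModelSpec(
            "severe_bleach",
            frozenset({"dhw:basin", "dhw:year", "dhw:basin:year"}),
        )
        assert "basin" not in spec.terms


class TestCandidateModels:
    def test_enumeration_size(self):
        # 5 main-effect structures x 5 DHW-interaction structures
        specs = candidate_models("moderate_bleach")
        assert len(specs) == 25
        assert len({s.terms for s in specs}) == 25  # deduplicated

    def test_full_three_way_model_present(self):
        terms = {
            frozenset(s.terms) for s in candidate_models("moderate_bleach")
        }
        full = frozenset(
            {"dhw", "basin", "year", "basin:year", "dhw:basin", "dhw:year",
             "dhw:basin:year"}
        )
        assert full in terms

    def test_common_intercept_variant_present(self):
        terms = {frozenset(s.terms) for s in candidate_models("severe_bleach")}
        assert frozenset({"dhw", "dhw:basin", "dhw:year", "dhw:basin:year"}) in terms

    def test_all_include_dhw(self):
        assert all("dhw" in s.terms for s in candidate_models("moderate_mortality"))


class TestBuildDesign:
    def three_by_three(self, spec_terms):
        rng = np.random.default_rng(0)
        n = 90
        df = obs_frame(
            rng.uniform(0, 10, n),
            rng.integers(0, 2, n),
            basin=np.repeat(["AP", "CA", "IM"], 30),
            year=np.tile(np.repeat(["2014-15", "2015-16", "2016-17"], 10), 3),
        )
        spec = ModelSpec("moderate_bleach", frozenset(spec_terms))
        return build_design(df, spec)

    def test_dhw_only_two_columns(self):
        X, y, g, info = self.three_by_three({"dhw"})
        assert X.shape[1] == 2
        assert info.names == ("(Intercept)", "dhw")

    def test_full_three_way_column_count(self):
        # 1 + 1 + 2 + 2 + 4 + 2 + 2 + 4 = 18 for 3 basins x 3 years
        X, _, _, info = self.three_by_three(
            {"dhw", "basin", "year", "basin:year", "dhw:basin", "dhw:year",
             "dhw:basin:year"}
        )
        assert X.shape[1] == 18 == len(info.names)

    def test_reference_levels(self):
        _, _, _, info = self.three_by_three({"dhw", "basin", "year"})
        assert info.basins[0] == "AP" and info.years[0] == "2014-15"
        assert "basin[CA]" in info.names and "year[2015-16]" in info.names

    def test_constrained_spec_shares_baseline_at_zero_dhw(self):
        _, _, _, info = self.three_by_three({"dhw", "dhw:basin"})
        X0 = design_matrix_for(info, [0.0, 0.0, 0.0], ["AP", "CA", "IM"], "2014-15")
        # at DHW = 0 all rows are the pure-intercept row: identical baselines
        assert np.allclose(X0, np.column_stack([np.ones(3), np.zeros((3, 3))]))

    def test_unknown_level_errors(self):
        _, _, _, info = self.three_by_three({"dhw", "basin"})
        with pytest.raises(ValueError, match="unknown basin"):
            design_matrix_for(info, [1.0], ["XX"], ["2014-15"])


class TestFixedLogistic:
    def test_intercept_only_closed_form(self):
        info = DesignInfo(
            spec=ModelSpec("moderate_bleach", frozenset({"dhw"})),
            basins=("AP",), years=("2014-15",), names=("(Intercept)",),
        )
        y = np.r_[np.ones(25), np.zeros(75)]
        fit = fit_logistic(np.ones((100, 1)), y, info)
        assert fit.beta[0] == pytest.approx(np.log(0.25 / 0.75), abs=1e-9)

    def test_recovers_simulated_coefficients(self):
        rng = np.random.default_rng(12)
        n = 5000
        dhw = rng.uniform(0, 12, n)
        y = (rng.random(n) < expit(-2.0 + 0.5 * dhw)).astype(int)
        df = obs_frame(dhw, y)
        X, yy, _, info = build_design(df, ModelSpec("moderate_bleach", frozenset({"dhw"})))
        fit = fit_logistic(X, yy, info)
        assert fit.beta == pytest.approx([-2.0, 0.5], abs=0.1)

    def test_agrees_with_independent_optimizer_on_50_rows(self, glmm_fixture):
        import statsmodels.api as sm

        d = glmm_fixture.iloc[:50]
        X = np.column_stack([np.ones(50), d["dhw"]])
        y = d["y"].to_numpy(float)
        oracle = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        info = DesignInfo(
            spec=ModelSpec("moderate_bleach", frozenset({"dhw"})),
            basins=("AP",), years=("2014-15",), names=("(Intercept)", "dhw"),
        )
        fit = fit_logistic(X, y, info)
        assert fit.beta == pytest.approx(oracle.params, abs=1e-6)
        assert fit.loglik == pytest.approx(oracle.llf, abs=1e-6)

    def test_matches_frozen_r_glm_on_full_fixture(self, glmm_obs):
        X, y, _, info = build_design(
            glmm_obs, ModelSpec("moderate_bleach", frozenset({"dhw"}))
        )
        fit = fit_logistic(X, y, info)
        assert fit.beta == pytest.approx(GLM_FIXED["beta"], abs=1e-7)
        assert fit.loglik == pytest.approx(GLM_FIXED["loglik"], abs=1e-6)

    def test_deviance_trace_monotone(self, glmm_obs):
        X, y, _, info = build_design(
            glmm_obs, ModelSpec("moderate_bleach", frozenset({"dhw"}))
        )
        fit = fit_logistic(X, y, info)
        assert np.all(np.diff(fit.deviance_trace) <= 1e-9)

    def test_separation_raises_with_trace(self):
        dhw = np.r_[np.zeros(20), np.full(20, 10.0)]
        y = np.r_[np.zeros(20), np.ones(20)]  # perfectly separated
        X, yy, _, info = build_design(
            obs_frame(dhw, y), ModelSpec("moderate_bleach", frozenset({"dhw"}))
        )
        with pytest.raises(SeparationError) as exc:
            fit_logistic(X, yy, info)
        assert len(exc.value.deviance_trace) > 1

    def test_ridge_fallback_returns_finite_fit(self):
        dhw = np.r_[np.zeros(20), np.full(20, 10.0)]
        y = np.r_[np.zeros(20), np.ones(20)]
        X, yy, _, info = build_design(
            obs_frame(dhw, y), ModelSpec("moderate_bleach", frozenset({"dhw"}))
        )
        fit = fit_logistic(X, yy, info, ridge=1e-3)
        assert np.all(np.isfinite(fit.beta))


class TestMixedLogistic:
    def test_matches_frozen_lme4_laplace(self, glmm_obs):
        X, y, g, info = build_design(
            glmm_obs, ModelSpec("moderate_bleach", frozenset({"dhw"}))
        )
        fit = fit_logistic_mixed(X, y, g, info)
        assert fit.beta == pytest.approx(LME4_LAPLACE["beta"], abs=2e-4)
        assert fit.sigma_u == pytest.approx(LME4_LAPLACE["sigma"], abs=2e-3)
        assert fit.loglik == pytest.approx(LME4_LAPLACE["loglik"], abs=1e-3)
        assert fit.aic == pytest.approx(LME4_LAPLACE["aic"], abs=2e-3)
        se = np.sqrt(np.diag(fit.vcov))
        assert se == pytest.approx(LME4_LAPLACE["se"], rel=2e-2)

    def test_matches_frozen_lme4_agq9(self, glmm_obs):
        X, y, g, info = build_design(
            glmm_obs, ModelSpec("moderate_bleach", frozenset({"dhw"}))
        )
        fit = fit_logistic_mixed(X, y, g, info, agq_points=9)
        assert fit.beta == pytest.approx(LME4_AGQ9["beta"], abs=2e-4)
        assert fit.sigma_u == pytest.approx(LME4_AGQ9["sigma"], abs=2e-3)
        assert fit.loglik == pytest.approx(LME4_AGQ9["loglik"], abs=1e-3)

    def test_reduces_to_fixed_fit_without_group_variance(self):
        rng = np.random.default_rng(1)
        n = 1500
        dhw = rng.uniform(0, 10, n)
        y = (rng.random(n) < expit(-2 + 0.5 * dhw)).astype(int)
        df = obs_frame(dhw, y, station=rng.integers(0, 30, n))
        X, yy, g, info = build_design(df, ModelSpec("moderate_bleach", frozenset({"dhw"})))
        fixed = fit_logistic(X, yy, info)
        mixed = fit_logistic_mixed(X, yy, g, info)
        assert mixed.sigma_u < 0.05
        assert mixed.beta == pytest.approx(fixed.beta, abs=2e-3)

    def test_mixed_loglik_at_least_fixed(self, glmm_obs):
        # nesting: sigma_u = 0 recovers the fixed model, so the mixed
        # maximum cannot be lower
        X, y, g, info = build_design(
            glmm_obs, ModelSpec("moderate_bleach", frozenset({"dhw"}))
        )
        fixed = fit_logistic(X, y, info)
        mixed = fit_logistic_mixed(X, y, g, info)
        assert mixed.loglik >= fixed.loglik - 1e-4

    def test_empirical_bayes_effects_shrink_toward_zero(self, glmm_obs):
        X, y, g, info = build_design(
            glmm_obs, ModelSpec("moderate_bleach", frozenset({"dhw"}))
        )
        fit = fit_logistic_mixed(X, y, g, info)
        assert len(fit.group_effects) == glmm_obs["station_id"].nunique()
        assert np.abs(fit.group_effects).max() < 4 * fit.sigma_u


class TestAICSelection:
    def test_aic_arithmetic(self, glmm_obs):
        X, y, g, info = build_design(
            glmm_obs, ModelSpec("moderate_bleach", frozenset({"dhw"}))
        )
        mixed = fit_logistic_mixed(X, y, g, info)
        # k counts fixed coefficients plus one for the random-intercept variance
        assert mixed.k_parameters == 3
        assert mixed.aic == pytest.approx(-2 * mixed.loglik + 2 * 3)

    def test_lower_aic_wins_even_with_lower_loglik(self):
        # -100/k=5 -> AIC 210 beats -99/k=8 -> AIC 214
        assert -2 * (-100) + 2 * 5 < -2 * (-99) + 2 * 8

    def test_nested_models_deviance_never_increases(self):
        rng = np.random.default_rng(3)
        n = 600
        dhw = rng.uniform(0, 10, n)
        basin = rng.choice(["AP", "CA"], n)
        y = (rng.random(n) < expit(-1 + 0.3 * dhw)).astype(int)
        df = obs_frame(dhw, y, basin=basin)
        small = ModelSpec("moderate_bleach", frozenset({"dhw"}), random_intercept=False)
        big = ModelSpec(
            "moderate_bleach", frozenset({"dhw", "basin", "dhw:basin"}),
            random_intercept=False,
        )
        f_small = fit_model(df, small)
        f_big = fit_model(df, big)
        assert f_big.loglik >= f_small.loglik - 1e-9

    def test_recovers_interaction_in_most_replicates(self):
        # data generated with a strong basin x DHW interaction: selection
        # should keep an interaction-containing spec nearly always
        hits = 0
        reps = 20
        specs = candidate_models("moderate_bleach", random_intercept=False)
        for seed in range(reps):
            rng = np.random.default_rng(100 + seed)
            n = 800
            dhw = rng.uniform(0, 12, n)
            basin = rng.choice(["AP", "CA"], n)
            eta = -2.0 + 0.15 * dhw + 0.55 * dhw * (basin == "CA")
            y = (rng.random(n) < expit(eta)).astype(int)
            df = obs_frame(dhw, y, basin=basin)
            best, table = select_by_aic(specs, df)
            if "dhw:basin" in best.spec.terms:
                hits += 1
        assert hits >= 0.9 * reps

    def test_table_sorted_and_best_is_minimum(self, obs_bleach):
        specs = [
            ModelSpec("moderate_bleach", frozenset({"dhw"}), random_intercept=False),
            ModelSpec("moderate_bleach", frozenset({"dhw", "basin"}), random_intercept=False),
            ModelSpec(
                "moderate_bleach", frozenset({"dhw", "basin", "year"}),
                random_intercept=False,
            ),
        ]
        best, table = select_by_aic(specs, obs_bleach)
        assert (table["aic"].diff().dropna() >= 0).all()
        assert best.aic == table["aic"].min()


class TestAccuracy:
    def fake_model(self, beta):
        spec = ModelSpec("moderate_bleach", frozenset({"dhw"}), random_intercept=False)
        info = DesignInfo(spec=spec, basins=("AP",), years=("2014-15",),
                          names=("(Intercept)", "dhw"))
        return FittedResponseModel(
            spec=spec, info=info, beta=np.asarray(beta), vcov=np.eye(2),
            sigma_u=0.0, loglik=0.0, aic=0.0, n_obs=0, converged=True,
        )

    def test_all_confident_and_correct(self):
        m = self.fake_model([0.4054651081, 0.0])  # p = 0.6 everywhere
        df = obs_frame(np.zeros(10), np.ones(10))
        assert prediction_accuracy(m, df) == 1.0

    def test_exact_half_predicts_negative(self):
        m = self.fake_model([0.0, 0.0])  # p = 0.5 exactly, strict > rule
        y = np.r_[np.ones(3), np.zeros(7)]
        df = obs_frame(np.zeros(10), y)
        assert prediction_accuracy(m, df) == 0.7

    def test_matches_bruteforce_recomputation(self, obs_bleach, bleach_model):
        model = bleach_model
        for conditional in (True, False):
            acc = prediction_accuracy(model, obs_bleach, use_random_effects=conditional)
            u = (
                np.array([model.station_effect(s) for s in obs_bleach["station_id"]])
                if conditional
                else 0.0
            )
            X = design_matrix_for(
                model.info,
                obs_bleach["dhw"].to_numpy(),
                obs_bleach["basin"].to_numpy(),
                obs_bleach["bleaching_year"].to_numpy(),
            )
            p = expit(X @ model.beta + u)
            brute = np.mean((p > 0.5) == obs_bleach["y"].to_numpy().astype(bool))
            assert acc == pytest.approx(brute, abs=1e-12)


class TestResponseCurve:
    def test_half_probability_at_zero_linear_predictor(self):
        m = TestAccuracy().fake_model([0.0, 0.0])
        m.dhw_domain = {("AP", "2014-15"): (0.0, 10.0)}
        curve = response_curve(m, "AP", "2014-15", np.array([0.0, 5.0]))
        assert np.allclose(curve.p_mean, 0.5)

    def test_ci_endpoints_inside_unit_interval_and_ordered(self, bleach_model):
        model = bleach_model
        curve = response_curve(model, "AP", "2015-16", np.linspace(0, 30, 50))
        assert np.all(curve.ci_lo > 0) and np.all(curve.ci_hi < 1)
        assert np.all(curve.ci_lo <= curve.p_mean) and np.all(curve.p_mean <= curve.ci_hi)

    def test_grid_trimmed_to_observed_domain(self, bleach_model):
        model = bleach_model
        lo, hi = model.dhw_domain[("AP", "2015-16")]
        with pytest.warns(UserWarning, match="trimmed"):
            curve = response_curve(model, "AP", "2015-16", np.array([lo, hi + 50.0]))
        assert curve.dhw.max() <= hi

    def test_ci_matches_parametric_bootstrap_oracle(self, bleach_model):
        model = bleach_model
        grid = np.array([2.0, 6.0, 10.0])
        curve = response_curve(model, "AP", "2015-16", grid, trim_to_domain=False)
        rng = np.random.default_rng(0)
        draws = rng.multivariate_normal(model.beta, model.vcov, size=4000)
        X = design_matrix_for(model.info, grid, "AP", "2015-16")
        p = expit(draws @ X.T)  # (4000, 3)
        lo, hi = np.quantile(p, [0.025, 0.975], axis=0)
        assert curve.ci_lo == pytest.approx(lo, abs=0.02)
        assert curve.ci_hi == pytest.approx(hi, abs=0.02)


class TestVariogram:
    def test_iid_residuals_flat_at_residual_variance(self):
        rng = np.random.default_rng(0)
        n = 400
        r = rng.normal(0, 1, n)
        lats, lons = rng.uniform(-10, 10, n), rng.uniform(100, 140, n)
        v = residual_variogram(r, lats, lons, bin_edges_km=np.arange(0, 4001, 500))
        filled = v.semivariance[v.pair_counts > 200]
        assert np.all(np.abs(filled - r.var()) < 0.25)

    def test_duplicated_points_first_bin_zero(self):
        r = np.array([0.7, 0.7, 0.7])
        lats = np.array([1.0, 1.0, 1.0])
        lons = np.array([2.0, 2.0, 2.0])
        v = residual_variogram(r, lats, lons, bin_edges_km=np.array([0.0, 100.0]))
        assert v.semivariance[0] == 0.0

    def test_empty_bins_are_nan_not_zero(self):
        r = np.array([0.0, 1.0])
        v = residual_variogram(
            r, np.array([0.0, 0.1]), np.array([0.0, 0.1]),
            bin_edges_km=np.array([0.0, 50.0, 5000.0]),
        )
        assert np.isnan(v.semivariance[1])
        assert v.pair_counts.sum() == 1  # n(n-1)/2 pairs within range

    def test_clustered_residuals_rise_at_short_range(self):
        # two tight spatial clusters with opposite residual signs: gamma
        # grows from (near-zero) within-cluster to high between-cluster
        rng = np.random.default_rng(2)
        n = 100
        cluster = np.repeat([0, 1], n // 2)
        lats = np.where(cluster == 0, 0.0, 8.0) + rng.normal(0, 0.2, n)
        lons = np.full(n, 120.0) + rng.normal(0, 0.2, n)
        r = np.where(cluster == 0, -1.0, 1.0) + rng.normal(0, 0.1, n)
        v = residual_variogram(r, lats, lons, bin_edges_km=np.arange(0, 1201, 300))
        assert v.semivariance[0] < 0.1
        assert v.semivariance[-1] > 1.0


class TestResiduals:
    def test_pearson_scaling(self, obs_bleach, bleach_model):
        model = bleach_model
        r = residuals(model, obs_bleach, kind="response")
        rp = residuals(model, obs_bleach, kind="pearson")
        assert np.all(np.abs(rp) >= np.abs(r) - 1e-12)  # p(1-p) <= 1/4 scales up
        assert np.all(np.abs(r) <= 1.0)
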