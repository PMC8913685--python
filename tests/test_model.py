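"""Design bookkeeping, Laplace ML fitting, model comparison, prediction."""

import math

import numpy as np
import pytest

from beechgrow.climate import aggregate_seasons, site_mean_ai
from beechgrow.model import (
    ModelSpec,
    build_design,
    compare_models,
    fit_glmm,
    marginal_loglik_agq,
    marginal_loglik_laplace,
    predict_bai,
)
from beechgrow.ringio import network_bai_table
from beechgrow.synthetic import (
    TrueParams,
    generate_monthly_climate,
    generate_sites,
    simulate_growth,
)
from tests.conftest import SMALL_SPEC


def enumerate_columns(spec: ModelSpec) -> int:
    """Independent combinatorial count of fixed-effect columns."""
    def width(v):
        smooth = v in ("lat", "alt") or v.startswith(("tmax", "tmin"))
        return spec.basis_df if smooth else 1

    mains = ["ai", "lat", "alt"] + [
        f"{v}_{s}" for v in spec.climate_vars for s in spec.seasons
    ]
    total = 1 + sum(width(v) for v in mains)  # intercept + expanded mains
    clim = [v for v in mains if v.startswith(("tmax", "tmin", "pp"))]
    pairs = []
    if "ai_geo" in spec.interaction_blocks:
        pairs += [("ai", "lat"), ("ai", "alt")]
    if "geo_geo" in spec.interaction_blocks:
        pairs += [("lat", "alt")]
    for blk, left in (("ai_cli", "ai"), ("lat_cli", "lat"), ("alt_cli", "alt")):
        if blk in spec.interaction_blocks:
            pairs += [(left, c) for c in clim]
    if spec.interaction_mode == "linear":
        total += len(pairs)
    elif spec.interaction_mode == "expanded":
        total += sum(width(a) * width(b) for a, b in pairs)
    if spec.include_ba_fixed:
        total += 1
    return total


class TestDesignBookkeeping:
    def test_canonical_spec_has_21_main_variables(self):
        spec = ModelSpec()
        assert spec.n_main_variables == 21
        # 3 site-level variables + 3 climate variables x 6 seasons
        assert len([v for v in spec.main_variables if v in ("ai", "lat", "alt")]) == 3
        assert len([v for v in spec.main_variables if "_" in v]) == 18

    @pytest.mark.parametrize("mode", ["none", "linear", "expanded"])
    @pytest.mark.parametrize("df", [1, 2, 3])
    def test_column_count_matches_combinatorial_enumeration(self, mode, df):
        spec = ModelSpec(basis_df=df, interaction_mode=mode)
        assert spec.n_fixed_columns() == enumerate_columns(spec)

    def test_built_design_width_matches_closed_form(self, small_design):
        assert small_design.X.shape[1] == SMALL_SPEC.n_fixed_columns()

    def test_training_columns_standardized(self, small_design):
        """Every fixed column except the intercept has mean ~0 and SD ~1."""
        X = small_design.X[:, 1:]
        assert np.abs(X.mean(axis=0)).max() < 1e-8
        assert np.abs(X.std(axis=0) - 1.0).max() < 1e-8

    def test_constant_variable_rejected_by_name(self, small_network, small_seasonal, small_bai):
        sites = [
            type(s)(s.site_id, s.lat, s.lon, s.alt, 25.0) for s in small_network.sites
        ]
        with pytest.raises(ValueError, match="'ai'"):
            build_design(small_bai, small_seasonal, sites, SMALL_SPEC)

    def test_unmatched_site_rejected(self, small_network, small_seasonal, small_bai):
        with pytest.raises(ValueError, match="missing"):
            build_design(small_bai, small_seasonal, small_network.sites[:3], SMALL_SPEC)

    def test_group_subsetting_keeps_intercept_and_ba(self, small_design):
        null = small_design.subset_groups(())
        assert null.col_names == ["(Intercept)", "ba_prev"]
        ai_only = small_design.subset_groups(("ai",))
        assert ai_only.col_names == ["(Intercept)", "ai", "ba_prev"]


def _tiny_instance():
    """2 trees x 5 years on a df-1 vocabulary (10 observations)."""
    spec = ModelSpec(seasons=("SUM",), basis_df=1, interaction_mode="none")
    truth = TrueParams(
        spec=spec, intercept=math.log(900.0), coef={"ba_prev": -0.05},
        re_sd_intercept=0.2, re_sd_slope=0.05, re_corr=0.0, gamma_shape=15.0,
    )
    sites = generate_sites(2, seed=1)
    monthly = generate_monthly_climate(sites, (1990, 2016), seed=2)
    ai = site_mean_ai(monthly, window=(1990, 2016))
    for s in sites:
        s.ai = float(ai[s.site_id])
    rings, _, scaler = simulate_growth(
        monthly, sites, truth, trees_per_site=1, year_range=(2012, 2016),
        seed=3, return_truth=True,
    )
    design = build_design(
        network_bai_table(rings), aggregate_seasons(monthly), sites, spec, scaler=scaler
    )
    return design, truth


class TestLikelihood:
    def test_laplace_matches_adaptive_quadrature(self):
        """On a tiny instance the Laplace marginal log-likelihood agrees with
        a 41-node adaptive Gauss-Hermite integration within 1e-3."""
        design, truth = _tiny_instance()
        assert design.n_obs == 10 and design.n_groups == 2
        beta = truth.beta_vector(design.col_names)
        for shape in (15.0, 5.0):
            lap = marginal_loglik_laplace(design, beta, truth.re_cov, shape)
            agq = marginal_loglik_agq(design, beta, truth.re_cov, shape, nodes=41)
            assert abs(lap - agq) < 1e-3

    def test_quadrature_converged_in_node_count(self):
        design, truth = _tiny_instance()
        beta = truth.beta_vector(design.col_names)
        a31 = marginal_loglik_agq(design, beta, truth.re_cov, 10.0, nodes=31)
        a51 = marginal_loglik_agq(design, beta, truth.re_cov, 10.0, nodes=51)
        assert abs(a31 - a51) < 1e-8


class TestFitting:
    @pytest.fixture(scope="class")
    def boundary_case(self):
        """Data simulated with (numerically) no random effects."""
        spec = ModelSpec(seasons=("SUM",), interaction_mode="none")
        truth = TrueParams(
            spec=spec, intercept=math.log(900.0), coef={"ba_prev": -0.05},
            re_sd_intercept=1e-9, re_sd_slope=1e-9, re_corr=0.0, gamma_shape=8.0,
        )
        sites = generate_sites(10, seed=4)
        monthly = generate_monthly_climate(sites, (1970, 2016), seed=5)
        ai = site_mean_ai(monthly, window=(1970, 2016))
        for s in sites:
            s.ai = float(ai[s.site_id])
        rings, _, scaler = simulate_growth(
            monthly, sites, truth, trees_per_site=3, year_range=(1980, 2016),
            seed=6, radius_jitter_sd=0.0, return_truth=True,
        )
        design = build_design(
            network_bai_table(rings), aggregate_seasons(monthly), sites, spec, scaler=scaler
        )
        return design, fit_glmm(design)

    def test_zero_re_truth_estimated_near_boundary(self, boundary_case):
        """With no true random effects the estimated RE variances collapse:
        at least one lands on the hard boundary and together they explain a
        negligible share (<2%) of the log-response variance — the residual
        share is half-chi-square sampling noise of a variance at zero."""
        design, fit = boundary_case
        re_var = np.diag(fit.re_cov)
        assert re_var.min() < 1e-6
        assert re_var.max() < 0.02 * np.var(np.log(design.y))
        assert fit.boundary

    def test_boundary_fit_matches_gamma_glm(self, boundary_case):
        """With the random effects at zero the fixed effects coincide with an
        independent gamma GLM fit (statsmodels)."""
        sm = pytest.importorskip("statsmodels.api")
        design, fit = boundary_case
        glm = sm.GLM(
            design.y, design.X, family=sm.families.Gamma(sm.families.links.Log())
        ).fit()
        np.testing.assert_allclose(fit.beta, glm.params, atol=5e-3)

    def test_aic_bookkeeping(self, small_fit):
        assert small_fit.n_params == len(small_fit.beta) + 4
        assert small_fit.aic == pytest.approx(
            2 * small_fit.n_params - 2 * small_fit.loglik
        )
        assert np.isfinite(small_fit.aic)
        cov = small_fit.re_cov
        assert cov[0, 1] == cov[1, 0]
        assert np.all(np.linalg.eigvalsh(cov) > -1e-12)

    def test_single_tree_rejected(self, small_design):
        from dataclasses import replace

        one = replace(
            small_design,
            group_idx=np.zeros(small_design.n_obs, dtype=int),
            group_labels=["only"],
        )
        with pytest.raises(ValueError, match="2 trees"):
            fit_glmm(one)


class TestComparison:
    def test_self_comparison_gives_zero_chisq(self, small_design):
        ladder = [("A", ("ai",)), ("B", ("ai",))]
        table = compare_models(small_design, ladder=ladder, max_outer=150)
        assert table["df"].tolist() == [0, 0]
        assert abs(table["chisq"].iloc[1]) < 0.5  # identical model refit
        assert table["aic"].iloc[0] == pytest.approx(table["aic"].iloc[1], abs=0.5)

    def test_df_equals_parameter_count_difference(self, small_design):
        ladder = [("Null", ()), ("AI", ("ai",)), ("AI+Geo", ("ai", "geo"))]
        table = compare_models(small_design, ladder=ladder, max_outer=150)
        ai_cols = sum(1 for g in small_design.col_groups if g == {"ai"})
        assert table.loc[1, "df"] == ai_cols
        assert table.loc[1, "vs"] == "Null"
        assert table.loc[2, "vs"] == "AI"
        assert (table["delta_aic"] >= 0).all()
        assert table["chisq"].dropna().min() >= 0


class TestPrediction:
    def test_population_prediction_is_exp_of_linear_predictor(self, small_fit, small_design):
        """Vectorized oracle: prediction equals exp(X beta) row by row."""
        meta = small_design.meta
        frame = _training_frame(small_design)
        pred = predict_bai(small_fit, frame, population_level=True)
        manual = np.exp(small_design.X @ small_fit.beta)
        np.testing.assert_allclose(pred, manual, rtol=1e-10)

    def test_tree_level_prediction_adds_blups(self, small_fit, small_design):
        frame = _training_frame(small_design)
        pred = predict_bai(small_fit, frame, population_level=False)
        bl = small_fit.blups.set_index("tree_code")
        eta = small_design.X @ small_fit.beta
        eta = (
            eta
            + bl.loc[frame["tree_code"], "b_intercept"].to_numpy()
            + bl.loc[frame["tree_code"], "b_ba_slope"].to_numpy() * small_design.z_ba
        )
        np.testing.assert_allclose(pred, np.exp(eta), rtol=1e-10)
        assert (pred > 0).all()

    def test_coefficient_bump_moves_log_prediction_linearly(self, small_fit, small_design):
        """Finite-difference check: adding delta to one coefficient changes
        log-predictions by delta times that column."""
        from dataclasses import replace

        frame = _training_frame(small_design)
        j = small_fit.col_names.index("pp_SUM")
        delta = 0.07
        beta2 = small_fit.beta.copy()
        beta2[j] += delta
        bumped = replace(small_fit, beta=beta2)
        p0 = predict_bai(small_fit, frame)
        p1 = predict_bai(bumped, frame)
        np.testing.assert_allclose(
            np.log(p1) - np.log(p0), delta * small_design.X[:, j], atol=1e-10
        )

    def test_ba_fixed_overrides_column(self, small_fit, small_design):
        frame = _training_frame(small_design).drop(columns=["ba_prev"])
        with pytest.raises(ValueError, match="ba_prev"):
            predict_bai(small_fit, frame)
        pred = predict_bai(small_fit, frame, ba_fixed=5e4)
        assert (pred > 0).all()

    def test_unknown_variable_vocabulary_rejected(self, small_fit, small_design):
        frame = _training_frame(small_design).drop(columns=["pp_SUM"])
        with pytest.raises(Exception):
            predict_bai(small_fit, frame, ba_fixed=5e4)


def _training_frame(design):
    """Reconstruct the raw covariate frame for the training rows."""
    # invert the stored var-level standardization (log vars exponentiated)
    scaler = design.scaler
    spec = design.spec
    z = {}
    X = design.X
    names = design.col_names
    frame = design.meta.copy()
    # raw values recovered from the stage-1 z of each linear main column
    for v in spec.main_variables:
        nm = spec.expanded_names(v)[0]
        j = names.index(nm)
        m_c, s_c = scaler.col_stats[nm]
        z_v = X[:, j] * s_c + m_c
        m, s = scaler.var_stats[v]
        t = z_v * s + m
        if spec.is_logged(v):
            offset = spec.pp_offset if v.startswith("pp_") else 0.0
            frame[v] = np.exp(t) - offset
        else:
            frame[v] = t
    m, s = scaler.var_stats["ba_prev"]
    frame["ba_prev"] = design.z_ba * s + m
    return frame
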