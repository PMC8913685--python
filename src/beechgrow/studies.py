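"""Self-contained simulation studies: parameter recovery, model-selection
behaviour, type-I error calibration, round-trip and masking oracles.

These run the whole stack on synthetic networks with known ground truth and
return plain dictionaries of summary numbers. They back both the test suite
and the reproduction script, so the reported figures always come from a
fresh end-to-end computation.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .climate import aggregate_seasons, apply_delta, site_mean_ai
from .model import ModelSpec, build_design, compare_models, fit_glmm
from .projection import applicability_domain, percent_change, period_mean, predict_grid, run_scenarios
from .ringio import network_bai_table
from .synthetic import (
    TrueParams,
    default_true_params,
    generate_monthly_climate,
    generate_network,
    generate_scenario_ensemble,
    generate_sites,
    simulate_growth,
)

__all__ = [
    "derive_seed",
    "parameter_recovery_study",
    "ladder_study",
    "type1_error_study",
    "bai_roundtrip_study",
    "ad_oracle_study",
    "scenario_study",
]


def derive_seed(master: int, *key: int) -> int:
    """Deterministic child seed below 2^31 from a master seed and index key."""
    ss = np.random.SeedSequence([int(master), *map(int, key)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


#: reduced-vocabulary spec used for the simulation studies: two growing-season
#: windows keep the fits fast while every variable group stays active
STUDY_SPEC = ModelSpec(seasons=("SPR", "SUM"), interaction_mode="linear")


def _simulate_and_design(
    truth: TrueParams,
    n_sites: int,
    trees_per_site: int,
    ring_years: tuple[int, int],
    climate_years: tuple[int, int],
    seed: int,
):
    sites = generate_sites(n_sites, derive_seed(seed, 1))
    monthly = generate_monthly_climate(sites, climate_years, seed=derive_seed(seed, 2))
    ai = site_mean_ai(monthly, window=climate_years)
    for s in sites:
        s.ai = float(ai[s.site_id])
    rings, _, scaler = simulate_growth(
        monthly,
        sites,
        truth,
        trees_per_site,
        year_range=ring_years,
        seed=derive_seed(seed, 3),
        return_truth=True,
    )
    bai = network_bai_table(rings)
    seasonal = aggregate_seasons(monthly)
    design = build_design(bai, seasonal, sites, truth.spec, scaler=scaler)
    return design


def parameter_recovery_study(
    seed: int = 1,
    n_seeds: int = 20,
    n_sites: int = 50,
    trees_per_site: int = 5,
    n_years: int = 60,
) -> dict:
    """Fit the growth model on data simulated from known parameters and
    report how often each true fixed effect lies within +-3 SE of its
    estimate, pooled over replicate networks (~15,000 observations each)."""
    truth = default_true_params(ModelSpec())
    within = 0
    total = 0
    per_seed = []
    for k in range(n_seeds):
        design = _simulate_and_design(
            truth,
            n_sites,
            trees_per_site,
            ring_years=(2016 - n_years + 1, 2016),
            climate_years=(2016 - n_years - 26, 2016),
            seed=derive_seed(seed, 100 + k),
        )
        fit = fit_glmm(design)
        beta_true = truth.beta_vector(design.col_names)
        se = np.where(fit.se > 0, fit.se, np.inf)
        ok = np.abs(fit.beta - beta_true) <= 3.0 * se
        within += int(ok.sum())
        total += ok.size
        per_seed.append(float(ok.mean()))
    return {
        "coverage": within / total,
        "n_coefficients": total,
        "n_seeds": n_seeds,
        "n_obs_per_seed": n_sites * trees_per_site * n_years,
        "per_seed": per_seed,
    }


def ladder_study(
    seed: int = 1,
    n_sites: int = 35,
    trees_per_site: int = 4,
    n_years: int = 40,
) -> dict:
    """Nested-model ladder on data where every variable group is truly
    active: the full model should attain the minimum AIC and every reduced
    model should beat the intercept-only null."""
    truth = default_true_params(STUDY_SPEC)
    design = _simulate_and_design(
        truth,
        n_sites,
        trees_per_site,
        ring_years=(2016 - n_years + 1, 2016),
        climate_years=(1950, 2016),
        seed=derive_seed(seed, 7),
    )
    table = compare_models(design)
    full = table.loc[table["label"] == "Full model", "aic"].iloc[0]
    null = table.loc[table["label"] == "Null model", "aic"].iloc[0]
    reduced = table.loc[~table["label"].isin(["Full model", "Null model"]), "aic"]
    return {
        "table": table,
        "full_model_best": bool((table.loc[table["label"] != "Full model", "aic"] > full).all()),
        "reduced_beat_null": bool((reduced < null).all()),
        "full_aic_margin": float(reduced.min() - full),
        "delta_aic_full": float(table.loc[table["label"] == "Full model", "delta_aic"].iloc[0]),
    }


def type1_error_study(
    seed: int = 1,
    n_replicates: int = 200,
    n_sites: int = 20,
    trees_per_site: int = 2,
    n_years: int = 25,
    alpha: float = 0.05,
) -> dict:
    """Size of the climate-block likelihood-ratio test when the climate
    coefficients are truly zero (aridity and geography stay active)."""
    spec = ModelSpec(seasons=("SPR", "SUM"), interaction_mode="none")
    base = default_true_params(spec)
    coef0 = {
        k: v for k, v in base.coef.items()
        if not k.startswith(("tmax", "tmin", "pp"))
    }
    truth = TrueParams(
        spec=spec,
        intercept=base.intercept,
        coef=coef0,
        re_sd_intercept=base.re_sd_intercept,
        re_sd_slope=base.re_sd_slope,
        re_corr=base.re_corr,
        gamma_shape=base.gamma_shape,
    )
    rejections = 0
    df = None
    for k in range(n_replicates):
        design = _simulate_and_design(
            truth,
            n_sites,
            trees_per_site,
            ring_years=(2016 - n_years + 1, 2016),
            climate_years=(1985, 2016),
            seed=derive_seed(seed, 500 + k),
        )
        full = fit_glmm(design, max_outer=250)
        reduced = fit_glmm(design.subset_groups(("ai", "geo")), max_outer=250)
        chisq = max(2.0 * (full.loglik - reduced.loglik), 0.0)
        df = full.n_params - reduced.n_params
        if stats.chi2.sf(chisq, df) < alpha:
            rejections += 1
    return {
        "rejection_rate": rejections / n_replicates,
        "n_replicates": n_replicates,
        "df": df,
        "alpha": alpha,
    }


def bai_roundtrip_study(
    seed: int = 1,
    n_sites: int = 20,
    trees_per_site: int = 3,
    n_years: int = 40,
) -> dict:
    """Disc-area conservation and simulate -> widths -> BAI round-trip.

    Conservation: per tree, sum(BAI) = pi (dbh/2)^2 - pi R0^2 exactly (up to
    float roundoff). Round-trip: reconstructed BAI differs from the simulated
    BAI only through the 0.01 mm width rounding; the error of each increment
    is bounded by the area effect of perturbing both bounding radii by the
    accumulated rounding offset.
    """
    net = _net(seed, n_sites, trees_per_site, n_years)
    bai = network_bai_table(net.rings)
    cons_err = 0.0
    for r in net.rings:
        sub = bai[bai["tree_code"] == r.tree_code]
        r0 = r.dbh_mm / 2.0 - float(r.widths.sum())
        expect = math.pi * ((r.dbh_mm / 2.0) ** 2 - r0**2)
        cons_err = max(cons_err, abs(sub["bai"].sum() - expect) / expect)
    merged = bai.merge(
        net.true_bai, on=["site_id", "tree_code", "year"], suffixes=("_rec", "_true")
    )
    # bound: each reconstructed radius is off by at most the accumulated
    # rounding (<= 0.005 mm per ring); the induced BAI error is at most
    # 2 * pi * R * delta + pi * delta^2 per bounding circle
    n_rings = merged.groupby("tree_code")["year"].rank()
    delta = 0.005 * n_rings.to_numpy()
    radius = np.sqrt((merged["ba_prev_true"] + merged["bai_true"]).to_numpy() / math.pi)
    bound = 2.0 * (2.0 * math.pi * radius * delta + math.pi * delta**2) + 1e-9
    err = np.abs(merged["bai_rec"] - merged["bai_true"]).to_numpy()
    return {
        "conservation_max_rel_err": cons_err,
        "roundtrip_max_err_mm2": float(err.max()),
        "roundtrip_within_bound": bool((err <= bound).all()),
        "n_trees": len(net.rings),
        "n_rings": int(len(merged)),
    }


def _net(seed, n_sites, trees_per_site, n_years):
    return generate_network(
        n_sites=n_sites,
        trees_per_site=trees_per_site,
        year_range=(2016 - n_years + 1, 2016),
        climate_range=(1950, 2016),
        seed=derive_seed(seed, 11),
    )


def ad_oracle_study(seed: int = 1, n_pixels: int = 1000, n_train_sites: int = 40) -> dict:
    """Applicability-domain mask versus an independent per-cell, per-variable
    double-loop range check on a random future grid."""
    rng = np.random.default_rng(derive_seed(seed, 13))
    seasons = list(ModelSpec().seasons)
    train = pd.DataFrame(
        {
            "site_id": np.repeat([f"T{i}" for i in range(n_train_sites)], len(seasons)),
            "season": seasons * n_train_sites,
            "tmax_mean": rng.normal(15, 5, n_train_sites * len(seasons)),
            "tmin_mean": rng.normal(5, 5, n_train_sites * len(seasons)),
            "pp_sum": rng.uniform(50, 400, n_train_sites * len(seasons)),
        }
    )
    future = pd.DataFrame(
        {
            "site_id": np.repeat([f"P{i}" for i in range(n_pixels)], len(seasons)),
            "season": seasons * n_pixels,
            "tmax_mean": rng.normal(15, 7, n_pixels * len(seasons)),
            "tmin_mean": rng.normal(5, 7, n_pixels * len(seasons)),
            "pp_sum": rng.uniform(20, 450, n_pixels * len(seasons)),
        }
    )
    mask = applicability_domain(train, future)
    # brute-force oracle: explicit loops over pixels, variables and seasons
    bounds = {}
    for var in ("tmax_mean", "tmin_mean", "pp_sum"):
        for season in seasons:
            tr = train.loc[train["season"] == season, var]
            bounds[(var, season)] = (tr.min(), tr.max())
    mismatches = 0
    for pix, grp in future.groupby("site_id"):
        outside = False
        for var in ("tmax_mean", "tmin_mean", "pp_sum"):
            for season in seasons:
                lo, hi = bounds[(var, season)]
                for v in grp.loc[grp["season"] == season, var]:
                    if v < lo or v > hi:
                        outside = True
        if bool(mask.inside[pix]) != (not outside):
            mismatches += 1
    return {
        "n_pixels": n_pixels,
        "mismatches": mismatches,
        "fraction_inside": mask.fraction_inside,
    }


def scenario_study(seed: int = 1, n_sites: int = 15, trees_per_site: int = 2) -> dict:
    """Small end-to-end projection: fit on a synthetic network, project both
    emission scenarios over the three future windows, and verify the
    zero-delta identity."""
    truth = default_true_params(STUDY_SPEC)
    sites = generate_sites(n_sites, derive_seed(seed, 21))
    monthly = generate_monthly_climate(sites, (1950, 2016), seed=derive_seed(seed, 22))
    ai = site_mean_ai(monthly)
    for s in sites:
        s.ai = float(ai[s.site_id])
    rings, _, scaler = simulate_growth(
        monthly, sites, truth, trees_per_site, year_range=(1987, 2016),
        seed=derive_seed(seed, 23), return_truth=True,
    )
    bai = network_bai_table(rings)
    seasonal = aggregate_seasons(monthly)
    design = build_design(bai, seasonal, sites, truth.spec, scaler=scaler)
    fit = fit_glmm(design, max_outer=250)

    from .climate import ScenarioDelta, ensemble_mean_delta

    members = generate_scenario_ensemble(sites, seed=derive_seed(seed, 24))
    deltas = {k: ensemble_mean_delta(t, p) for k, (t, p) in members.items()}
    results = run_scenarios(
        fit, seasonal, sites, deltas, training_seasonal=seasonal, baseline_window=(1986, 2016)
    )
    # zero-delta identity on one combination
    zero = deltas[next(iter(deltas))]
    zero = ScenarioDelta(zero.scenario, zero.window, zero.table.assign(dtmax=0.0, dtmin=0.0, dpp=0.0))
    base = seasonal[(seasonal["year"] >= 1985) & (seasonal["year"] <= 2016)]
    g0 = predict_grid(fit, base, sites)
    g1 = predict_grid(fit, apply_delta(base, zero), sites)
    m0 = period_mean(g0, (1986, 2016))
    m1 = period_mean(g1, (1986, 2016))
    zero_delta_max_pct = float(np.abs(percent_change(m0.to_numpy(), m1.to_numpy())).max())
    return {
        "n_outputs": len(results),
        "scenarios": sorted({r.scenario for r in results}),
        "windows": sorted({r.window for r in results}),
        "zero_delta_max_abs_pct": zero_delta_max_pct,
        "results": results,
        "model": fit,
    }
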