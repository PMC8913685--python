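"""End-to-end orchestration: synthetic network -> BAI -> seasonal climate ->
GLMM fit -> validation ladder -> historical and scenario projections.

Every stage reads and writes plain CSV/JSON/YAML artifacts in one output
directory, so stages can be rerun individually from the CLI; a manifest
records the config hash, seeds and library versions for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .climate import SiteMeta, aggregate_seasons, ensemble_mean_delta, site_mean_ai
from .model import FittedGrowthModel, ModelSpec, build_design, compare_models, fit_glmm
from .projection import (
    REFERENCE_BA,
    percent_change,
    period_mean,
    predict_grid,
    run_scenarios,
)
from .ringio import network_bai_table
from .synthetic import (
    generate_monthly_climate,
    generate_network,
    generate_scenario_ensemble,
    write_network,
)

__all__ = ["PipelineConfig", "run_pipeline", "report", "default_config"]

log = logging.getLogger("beechgrow.pipeline")


def default_config() -> dict:
    return {
        "seed": 1,
        "synthetic": {
            "n_sites": 20,
            "trees_per_site": 3,
            "ring_years": [1950, 2016],
            "climate_years": [1901, 2016],
            "trend": 0.2,
        },
        "model": {
            "basis_df": 2,
            "interaction_mode": "linear",
            "max_outer": 300,
        },
        "windows": {
            "historical": [[1955, 1985], [1986, 2016]],
            "baseline": [1986, 2016],
            "future": [[2020, 2050], [2040, 2070], [2060, 2090]],
            "training_climate": [1901, 2016],
            "model_period": [1950, 2016],
            "ai_window": [1950, 2016],
        },
        "scenarios": ["SSP1-2.6", "SSP5-8.5"],
        "grid": {"nx": 6, "ny": 6},
        "reference_ba": REFERENCE_BA,
        "run_ladder": True,
    }


@dataclass
class PipelineConfig:
    """Validated pipeline settings (windows, seeds, model spec, grid)."""

    raw: dict

    def __post_init__(self) -> None:
        merged = default_config()
        for k, v in self.raw.items():
            if isinstance(v, dict) and isinstance(merged.get(k), dict):
                merged[k] = {**merged[k], **v}
            else:
                merged[k] = v
        self.raw = merged
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")
        for name, win in self.all_windows():
            if win[0] > win[1]:
                raise ValueError(f"window {name} has start > end: {win}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def all_windows(self):
        w = self.raw["windows"]
        yield from (("historical", tuple(h)) for h in w["historical"])
        yield ("baseline", tuple(w["baseline"]))
        yield from (("future", tuple(f)) for f in w["future"])
        yield ("training_climate", tuple(w["training_climate"]))
        yield ("model_period", tuple(w["model_period"]))
        yield ("ai_window", tuple(w["ai_window"]))

    @property
    def seed(self) -> int:
        return self.raw["seed"]

    @property
    def model_spec(self) -> ModelSpec:
        m = self.raw["model"]
        return ModelSpec(
            basis_df=m.get("basis_df", 2),
            interaction_mode=m.get("interaction_mode", "linear"),
        )

    def window(self, name: str):
        return tuple(self.raw["windows"][name])

    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        """Per-stage seed derived from the master seed: low 31 bits of the
        SHA-256 of '<master>:<stage>'."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _setup_logging(outdir: str, level: str = "INFO") -> None:
    handlers = [logging.StreamHandler()]
    handlers.append(logging.FileHandler(os.path.join(outdir, "pipeline.log")))
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


def _grid_metas(config: PipelineConfig) -> list[SiteMeta]:
    """Coarse lattice over the network bounding box; altitude follows the
    same northward-tapering ceiling as the site generator."""
    from .synthetic import ALT_RANGE, LAT_RANGE, LON_RANGE

    nx = config.raw["grid"]["nx"]
    ny = config.raw["grid"]["ny"]
    lons = np.linspace(LON_RANGE[0], LON_RANGE[1], nx)
    lats = np.linspace(LAT_RANGE[0], LAT_RANGE[1], ny)
    metas = []
    for iy, la in enumerate(lats):
        alt_cap = ALT_RANGE[1] - 1600.0 * (la - LAT_RANGE[0]) / (LAT_RANGE[1] - LAT_RANGE[0])
        for ix, lo in enumerate(lons):
            metas.append(
                SiteMeta(
                    site_id=f"P{iy:02d}{ix:02d}",
                    lat=float(la),
                    lon=float(lo),
                    alt=float(0.4 * alt_cap),
                )
            )
    return metas


def run_pipeline(config: PipelineConfig, outdir: str, log_level: str = "INFO") -> dict:
    """Execute all stages and write artifacts + manifest; returns the manifest."""
    os.makedirs(outdir, exist_ok=True)
    _setup_logging(outdir, log_level)
    spec = config.model_spec
    syn = config.raw["synthetic"]

    log.info("stage simulate: %d sites x %d trees", syn["n_sites"], syn["trees_per_site"])
    network = generate_network(
        n_sites=syn["n_sites"],
        trees_per_site=syn["trees_per_site"],
        year_range=tuple(syn["ring_years"]),
        climate_range=tuple(syn["climate_years"]),
        seed=config.stage_seed("simulate"),
        trend=syn["trend"],
    )
    write_network(network, outdir)

    log.info("stage bai: converting %d ring series", len(network.rings))
    bai = network_bai_table(network.rings)
    bai.to_csv(os.path.join(outdir, "bai.csv"), index=False)

    log.info("stage climate: seasonal aggregation + aridity")
    seasonal = aggregate_seasons(network.climate)
    seasonal.to_csv(os.path.join(outdir, "seasonal.csv"), index=False)

    lo, hi = config.window("model_period")
    bai_fit = bai[(bai["year"] >= lo) & (bai["year"] <= hi)]
    log.info("stage fit: %d observations, %d fixed columns", len(bai_fit), spec.n_fixed_columns())
    design = build_design(bai_fit, seasonal, network.sites, spec)
    fit = fit_glmm(design, max_outer=config.raw["model"]["max_outer"])
    fit.save(os.path.join(outdir, "model.json"))
    log.info("fit done: loglik=%.2f aic=%.2f shape=%.2f", fit.loglik, fit.aic, fit.gamma_shape)

    if config.raw["run_ladder"]:
        log.info("stage compare: 8-model validation ladder")
        table = compare_models(design, max_outer=config.raw["model"]["max_outer"])
        table.to_csv(os.path.join(outdir, "comparison.csv"), index=False)

    n_outputs = project_stage(config, fit, outdir)

    manifest = {
        "beechgrow_version": __version__,
        "config": config.raw,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": {s: config.stage_seed(s) for s in ("simulate", "grid_climate", "scenarios")},
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "artifacts": {
            "model": "model.json",
            "comparison": "comparison.csv" if config.raw["run_ladder"] else None,
            "historical_change": "historical_change.csv",
            "scenario_changes": "scenario_changes.csv",
            "n_scenario_outputs": n_outputs,
        },
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    log.info("pipeline complete: %d scenario outputs", n_outputs)
    return manifest


def project_stage(config: PipelineConfig, fit: FittedGrowthModel, outdir: str) -> int:
    """Historical change map + six scenario projections on a coarse grid.

    Returns the number of scenario outputs written.
    """
    syn = config.raw["synthetic"]
    log.info("stage project: historical change map")
    metas = _grid_metas(config)
    grid_monthly = generate_monthly_climate(
        metas,
        year_range=tuple(config.window("training_climate")),
        trend=syn["trend"],
        seed=config.stage_seed("grid_climate"),
    )
    ai = site_mean_ai(grid_monthly, window=config.window("ai_window"))
    for m in metas:
        m.ai = float(ai[m.site_id])
    grid_seasonal = aggregate_seasons(grid_monthly)
    ref_ba = config.raw["reference_ba"]
    win_a, win_b = (tuple(w) for w in config.raw["windows"]["historical"])
    hist_grid = predict_grid(fit, grid_seasonal, metas, ba_fixed=ref_ba)
    mean_a = period_mean(hist_grid, win_a)
    mean_b = period_mean(hist_grid, win_b)
    hist = pd.DataFrame(
        {
            "site_id": mean_a.index,
            "lat": [m.lat for m in metas],
            "lon": [m.lon for m in metas],
            "mean_a": mean_a.to_numpy(),
            "mean_b": mean_b.reindex(mean_a.index).to_numpy(),
        }
    )
    hist["pct_change"] = percent_change(hist["mean_a"], hist["mean_b"])
    hist.to_csv(os.path.join(outdir, "historical_change.csv"), index=False)

    log.info("stage project: %d scenario combinations", len(config.raw["scenarios"]) * len(config.raw["windows"]["future"]))
    future_windows = tuple(tuple(w) for w in config.raw["windows"]["future"])
    members = generate_scenario_ensemble(
        metas,
        future_windows=future_windows,
        scenarios=tuple(config.raw["scenarios"]),
        seed=config.stage_seed("scenarios"),
    )
    deltas = {k: ensemble_mean_delta(t, p) for k, (t, p) in members.items()}
    results = run_scenarios(
        fit,
        grid_seasonal,
        metas,
        deltas,
        training_seasonal=grid_seasonal,
        ba_fixed=ref_ba,
        baseline_window=config.window("baseline"),
        scenarios=tuple(config.raw["scenarios"]),
        future_windows=future_windows,
    )
    rows = []
    geo = {m.site_id: (m.lat, m.lon) for m in metas}
    for res in results:
        cm = res.change_map.copy()
        cm["scenario"] = res.scenario
        cm["window"] = f"{res.window[0]}-{res.window[1]}"
        cm["lat"] = cm["site_id"].map(lambda s: geo[s][0])
        cm["lon"] = cm["site_id"].map(lambda s: geo[s][1])
        cm["inside_ad"] = cm["site_id"].map(res.ad_mask.inside)
        rows.append(cm)
    scen_df = pd.concat(rows, ignore_index=True)
    scen_df.to_csv(os.path.join(outdir, "scenario_changes.csv"), index=False)
    return len(results)


def report(outdir: str, band_width: float = 5.0) -> pd.DataFrame:
    """Latitude-band mean percent changes and AD coverage per scenario run."""
    path = os.path.join(outdir, "scenario_changes.csv")
    hist_path = os.path.join(outdir, "historical_change.csv")
    if not (os.path.exists(path) and os.path.exists(hist_path)):
        raise FileNotFoundError(f"missing projection artifacts in {outdir!r}; run the pipeline first")
    scen = pd.read_csv(path)
    hist = pd.read_csv(hist_path)
    hist = hist.assign(scenario="historical", window="historical", inside_ad=True)
    both = pd.concat([scen, hist[scen.columns.intersection(hist.columns)]], ignore_index=True)
    both["lat_band"] = (both["lat"] // band_width) * band_width
    out = (
        both.groupby(["scenario", "window", "lat_band"])
        .agg(
            mean_pct_change=("pct_change", "mean"),
            ad_inside_fraction=("inside_ad", "mean"),
            n_pixels=("site_id", "size"),
        )
        .reset_index()
    )
    return out
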