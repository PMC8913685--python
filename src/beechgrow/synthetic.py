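"""Synthetic multi-site beech network with known ground truth.

Generates the statistical structure the downstream analysis assumes: a site
network spanning the species' European range (5.8-28.4 degE, 38.8-58.5 degN,
1-1900 m a.s.l., annual climate inside the 500-2000 mm / 3.8-13.5 degC
envelope), monthly climate with a seasonal cycle, lapse-rate gradients, AR(1)
interannual persistence and an optional warming trend, tree ring series grown
forward from the gamma growth model under known parameters, and per-model
climate-scenario delta ensembles.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .climate import SEASONS, ScenarioDelta, SiteMeta, aggregate_seasons, seasonal_wide, site_mean_ai
from .model import ModelSpec, Scaler, compute_scaler, design_from_frame
from .ringio import RingSeries, write_rwl

__all__ = [
    "TrueParams",
    "SyntheticNetwork",
    "SimulationError",
    "default_true_params",
    "generate_sites",
    "generate_monthly_climate",
    "simulate_growth",
    "generate_scenario_ensemble",
    "generate_network",
    "write_network",
]

# Geographic bounding box and elevation limits of the emulated network.
LAT_RANGE = (38.8, 58.5)
LON_RANGE = (5.8, 28.4)
ALT_RANGE = (1.0, 1900.0)


class SimulationError(RuntimeError):
    pass


@dataclass
class TrueParams:
    """Ground-truth parameters of the generating growth model.

    ``coef`` maps design column names (as produced by the model's design
    builder: ``ai``, ``lat^1``, ``tmax_SUM^2``, ``ai:pp_SUM``, ``ba_prev``,
    ...) to coefficients on the standardized scale; absent columns are zero.
    ``ba_stats`` fixes the (center, scale) used to standardize previous basal
    area, since BA is endogenous to the simulation.
    """

    spec: ModelSpec
    intercept: float
    coef: dict[str, float]
    re_sd_intercept: float
    re_sd_slope: float
    re_corr: float
    gamma_shape: float
    ba_stats: tuple[float, float] = (30000.0, 20000.0)

    def __post_init__(self) -> None:
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be > 0")
        if abs(self.re_corr) > 1:
            raise ValueError("|re_corr| must be <= 1")
        if self.re_sd_intercept < 0 or self.re_sd_slope < 0:
            raise ValueError("random-effect SDs must be >= 0")
        vocab = set(_design_column_names(self.spec))
        unknown = set(self.coef) - vocab
        if unknown:
            raise ValueError(f"coefficients outside the design vocabulary: {sorted(unknown)[:5]}")

    @property
    def re_cov(self) -> np.ndarray:
        s1, s2, r = self.re_sd_intercept, self.re_sd_slope, self.re_corr
        return np.array([[s1**2, r * s1 * s2], [r * s1 * s2, s2**2]])

    def beta_vector(self, col_names: list[str]) -> np.ndarray:
        beta = np.zeros(len(col_names))
        for i, nm in enumerate(col_names):
            if nm == "(Intercept)":
                beta[i] = self.intercept
            else:
                beta[i] = self.coef.get(nm, 0.0)
        return beta


def _design_column_names(spec: ModelSpec) -> list[str]:
    names: list[str] = []
    for v in spec.main_variables:
        names += spec.expanded_names(v)
    if spec.interaction_mode == "linear":
        names += [f"{a}:{b}" for a, b in spec.interaction_pairs()]
    elif spec.interaction_mode == "expanded":
        for a, b in spec.interaction_pairs():
            names += [f"{na}:{nb}" for na in spec.expanded_names(a) for nb in spec.expanded_names(b)]
    if spec.include_ba_fixed:
        names.append("ba_prev")
    return names


def default_true_params(spec: ModelSpec | None = None) -> TrueParams:
    """Moderate, ecologically signed ground truth with every variable group
    active: warm-season heat hurts, growing-season rain helps, geography and
    aridity modulate the climate response."""
    spec = spec or ModelSpec()
    coef = {
        "ai": 0.22,
        "lat^1": -0.15,
        "lat^2": -0.05,
        "alt^1": -0.12,
        "alt^2": -0.04,
        "tmax_SUM^1": -0.10,
        "tmax_SUM^2": -0.04,
        "tmax_pSUM^1": -0.05,
        "tmax_SPR^1": 0.06,
        "tmin_WIN^1": 0.05,
        "pp_SUM": 0.12,
        "pp_SPR": 0.06,
        "pp_pSUM": 0.04,
        "ai:lat": 0.08,
        "ai:alt": 0.06,
        "lat:alt": -0.06,
        "ai:tmax_SUM": 0.08,
        "ai:pp_SUM": -0.10,
        "lat:tmax_SUM": 0.07,
        "alt:tmax_SUM": 0.07,
        "lat:pp_SUM": -0.10,
        "alt:pp_SUM": -0.08,
        "ba_prev": -0.05,
    }
    coef = {k: v for k, v in coef.items() if k in set(_design_column_names(spec))}
    return TrueParams(
        spec=spec,
        intercept=math.log(900.0),
        coef=coef,
        re_sd_intercept=0.25,
        re_sd_slope=0.08,
        re_corr=-0.2,
        gamma_shape=8.0,
    )


@dataclass
class SyntheticNetwork:
    sites: list[SiteMeta]
    climate: pd.DataFrame
    rings: list[RingSeries]
    truth: TrueParams
    seed: int
    true_bai: pd.DataFrame = field(repr=False, default=None)
    scaler: Scaler = field(repr=False, default=None)

    def __post_init__(self) -> None:
        site_ids = {s.site_id for s in self.sites}
        for r in self.rings:
            if r.site_id not in site_ids:
                raise ValueError(f"ring series {r.tree_code} references unknown site {r.site_id}")
        cyrs = set(self.climate["year"].unique())
        for r in self.rings:
            if not {int(y) for y in r.years} <= cyrs:
                raise ValueError(f"ring years of {r.tree_code} outside the climate record")


# ---------------------------------------------------------------------------
# Sites
# ---------------------------------------------------------------------------

def generate_sites(n_sites: int, seed: int) -> list[SiteMeta]:
    """Uniform site placement in the network bounding box.

    Maximum altitude tapers northward (treeline sites occur in the south),
    keeping every site inside the species' climate envelope once climate is
    generated.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    lat = rng.uniform(*LAT_RANGE, n_sites)
    lon = rng.uniform(*LON_RANGE, n_sites)
    alt_max = ALT_RANGE[1] - 1600.0 * (lat - LAT_RANGE[0]) / (LAT_RANGE[1] - LAT_RANGE[0])
    alt = rng.uniform(ALT_RANGE[0], alt_max)
    return [
        SiteMeta(site_id=f"S{i:03d}", lat=float(lat[i]), lon=float(lon[i]), alt=float(alt[i]))
        for i in range(n_sites)
    ]


# ---------------------------------------------------------------------------
# Monthly climate
# ---------------------------------------------------------------------------

def _site_normals(sites: list[SiteMeta], rng: np.random.Generator):
    """Long-term site mean temperature (degC) and precipitation (mm/yr)."""
    lat = np.array([s.lat for s in sites])
    alt_km = np.array([s.alt for s in sites]) / 1000.0
    # lapse/latitude gradients plus substantial independent site variation
    # (exposure, continentality), so aridity is not a deterministic function
    # of geography
    t = 13.3 - 0.33 * (lat - LAT_RANGE[0]) - 4.5 * alt_km + rng.normal(0.0, 0.6, len(sites))
    t = np.clip(t, 4.6, 12.6)
    p = 700.0 + 380.0 * alt_km + 11.0 * (lat - LAT_RANGE[0]) + rng.normal(0.0, 120.0, len(sites))
    p = np.clip(p, 540.0, 1900.0)
    return t, p


def generate_monthly_climate(
    sites: list[SiteMeta],
    year_range: tuple[int, int] = (1901, 2016),
    trend: float = 0.2,
    seed: int = 0,
    ar1: float = 0.3,
    annual_sd: float = 0.5,
    month_sd: float = 0.3,
    prcp_cv: float = 0.25,
    diurnal_range: float = 7.0,
    dtr_sd: float = 1.2,
) -> pd.DataFrame:
    """Monthly tmax/tmin/prcp per site.

    Sinusoidal seasonal cycle around a site normal set by latitude and a
    4.5 degC/km lapse rate; interannual AR(1) anomalies; ``trend`` in degC
    per decade, centered on the period midpoint so site means stay on their
    normals. Setting trend and all noise amplitudes to zero repeats the same
    year verbatim.
    """
    y0, y1 = year_range
    if y0 > y1:
        raise ValueError("empty year_range")
    rng = np.random.default_rng(seed)
    t_site, p_site = _site_normals(sites, rng)
    years = np.arange(y0, y1 + 1)
    n_y = years.size
    months = np.arange(1, 13)
    cyc = np.cos(2.0 * math.pi * (months - 7) / 12.0)
    pcyc = 1.0 + 0.2 * np.cos(2.0 * math.pi * (months - 1) / 12.0)
    trend_y = trend * (years - years.mean()) / 10.0
    frames = []
    for i, site in enumerate(sites):
        amp = 8.5 + 0.1 * (site.lat - LAT_RANGE[0])
        innov = rng.normal(0.0, annual_sd * math.sqrt(max(1.0 - ar1**2, 0.0)), n_y)
        a = np.empty(n_y)
        prev = rng.normal(0.0, annual_sd) if annual_sd > 0 else 0.0
        for k in range(n_y):
            prev = ar1 * prev + innov[k]
            a[k] = prev
        tm = t_site[i] + amp * cyc[None, :] + (a + trend_y)[:, None] + rng.normal(
            0.0, month_sd, (n_y, 12)
        )
        # diurnal range varies independently of the mean anomaly, so tmax and
        # tmin carry partially independent information (as in observations)
        dtr = diurnal_range + rng.normal(0.0, dtr_sd, (n_y, 12)) if dtr_sd > 0 else np.full((n_y, 12), diurnal_range)
        dtr = np.clip(dtr, 2.0, None)
        tmax = tm + dtr / 2.0
        tmin = tm - dtr / 2.0
        pfac = (
            np.exp(rng.normal(0.0, prcp_cv, (n_y, 12)) - prcp_cv**2 / 2.0)
            if prcp_cv > 0
            else np.ones((n_y, 12))
        )
        prcp = p_site[i] / 12.0 * pcyc[None, :] * pfac / pcyc.mean()
        frames.append(
            pd.DataFrame(
                {
                    "site_id": site.site_id,
                    "year": np.repeat(years, 12),
                    "month": np.tile(months, n_y),
                    "tmax": tmax.ravel(),
                    "tmin": tmin.ravel(),
                    "prcp": prcp.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Forward growth simulation
# ---------------------------------------------------------------------------

def simulate_growth(
    monthly: pd.DataFrame,
    sites: list[SiteMeta],
    truth: TrueParams,
    trees_per_site: int,
    initial_radius: float = 5.0,
    year_range: tuple[int, int] | None = None,
    seed: int = 0,
    radius_jitter_sd: float = 0.1,
    return_truth: bool = False,
):
    """Grow trees forward from the gamma growth model.

    Per tree: draw a correlated random intercept/BA-slope pair, then iterate
    years forming the linear predictor on the generating scaler, drawing
    ``BAI ~ Gamma(shape, mean=exp(eta))``, accumulating basal area, and
    emitting ring widths rounded to 0.01 mm (the measurement precision).
    The recorded DBH is twice the final radius implied by the rounded widths.

    With ``return_truth`` also returns (exact BAI table, scaler).
    """
    if trees_per_site < 1:
        raise ValueError("trees_per_site must be >= 1")
    rng = np.random.default_rng(seed)
    spec = truth.spec
    seasonal = aggregate_seasons(monthly)
    wide = seasonal_wide(seasonal)
    if year_range is not None:
        wide = wide[(wide["year"] >= year_range[0]) & (wide["year"] <= year_range[1])]
    if wide.empty:
        raise ValueError("no complete seasonal years in the requested range")
    site_df = pd.DataFrame(
        {"site_id": [s.site_id for s in sites], "lat": [s.lat for s in sites],
         "alt": [s.alt for s in sites], "ai": [s.ai for s in sites]}
    )
    if site_df["ai"].isna().any():
        ai = site_mean_ai(monthly, window=(int(monthly["year"].min()), int(monthly["year"].max())))
        site_df["ai"] = site_df["site_id"].map(ai)
        for s in sites:
            s.ai = float(ai[s.site_id])
    frame = wide.merge(site_df, on="site_id", validate="many_to_one")
    scaler = compute_scaler(frame, spec, ba_stats=truth.ba_stats)
    dm = design_from_frame(frame, spec, scaler, with_response=False)
    beta = truth.beta_vector(dm.col_names)
    i_ba = dm.col_names.index("ba_prev") if spec.include_ba_fixed else None
    beta_ba = beta[i_ba] if i_ba is not None else 0.0
    eta_cov = dm.X @ beta  # BA column is zero here; its term is added per year
    cov = pd.DataFrame({"site_id": frame["site_id"], "year": frame["year"], "eta_cov": eta_cov})

    s1, s2, r = truth.re_sd_intercept, truth.re_sd_slope, truth.re_corr
    L = np.array([[s1, 0.0], [r * s2, s2 * math.sqrt(max(1.0 - r**2, 0.0))]])
    mba, sba = truth.ba_stats

    series: list[RingSeries] = []
    truth_rows = []
    for site in sites:
        sub = cov[cov["site_id"] == site.site_id].sort_values("year")
        yrs = sub["year"].to_numpy()
        etas = sub["eta_cov"].to_numpy()
        for t_idx in range(trees_per_site):
            code = f"{site.site_id}T{t_idx:02d}"
            b = L @ rng.standard_normal(2)
            r0 = initial_radius * math.exp(rng.normal(0.0, radius_jitter_sd)) if radius_jitter_sd > 0 else initial_radius
            radius = r0
            ba = math.pi * radius**2
            widths = []
            for yr, eta_c in zip(yrs, etas):
                z_ba = (ba - mba) / sba
                eta = eta_c + b[0] + (beta_ba + b[1]) * z_ba
                if not np.isfinite(eta) or abs(eta) > 30:
                    raise SimulationError(
                        f"non-finite/extreme linear predictor at site {site.site_id}, year {yr}"
                    )
                mu = math.exp(eta)
                bai = rng.gamma(truth.gamma_shape, mu / truth.gamma_shape)
                truth_rows.append((site.site_id, code, int(yr), bai, ba))
                ba += bai
                new_radius = math.sqrt(ba / math.pi)
                widths.append(new_radius - radius)
                radius = new_radius
            w = np.round(np.asarray(widths), 2)
            w[w < 0.01] = 0.01  # measurement floor at the 0.01 mm precision
            dbh = 2.0 * (r0 + float(w.sum()))
            series.append(
                RingSeries(
                    tree_code=code,
                    site_id=site.site_id,
                    first_year=int(yrs[0]),
                    widths=w,
                    dbh_mm=dbh,
                )
            )
    if return_truth:
        true_bai = pd.DataFrame(
            truth_rows, columns=["site_id", "tree_code", "year", "bai", "ba_prev"]
        )
        return series, true_bai, scaler
    return series


# ---------------------------------------------------------------------------
# Scenario ensembles
# ---------------------------------------------------------------------------

#: ensemble-mean warming (degC) per future window, loosely CMIP6-like
_SCENARIO_WARMING = {
    "SSP1-2.6": (1.0, 1.3, 1.4),
    "SSP5-8.5": (1.6, 2.6, 3.8),
}
#: precipitation signal amplitude (mm/season per future window)
_SCENARIO_DPP = {
    "SSP1-2.6": (5.0, 8.0, 10.0),
    "SSP5-8.5": (10.0, 18.0, 25.0),
}


def generate_scenario_ensemble(
    sites: list[SiteMeta],
    n_temp_models: int = 21,
    n_precip_models: int = 26,
    historic_window: tuple[int, int] = (1985, 2014),
    future_windows: tuple[tuple[int, int], ...] = ((2020, 2050), (2040, 2070), (2060, 2090)),
    scenarios: tuple[str, ...] = ("SSP1-2.6", "SSP5-8.5"),
    seed: int = 0,
    member_sd_t: float = 0.3,
    member_sd_p: float = 8.0,
) -> dict[tuple[str, tuple[int, int]], tuple[list[ScenarioDelta], list[ScenarioDelta]]]:
    """Per-model delta sets (future minus historic climatology) per scenario
    and future window.

    Warming grows with the scenario and window; the precipitation signal is
    latitude-dependent (drying south of ~49 degN, wetting north of it), with
    per-model offsets emulating ensemble spread. Returns
    ``{(scenario, window): (temp_members, precip_members)}``.
    """
    if n_temp_models < 1 or n_precip_models < 1:
        raise ValueError("model counts must be >= 1")
    h0, h1 = historic_window
    for w0, w1 in future_windows:
        if w0 <= h1 and h0 <= w1:
            raise ValueError(f"future window {(w0, w1)} overlaps the historic window {historic_window}")
    rng = np.random.default_rng(seed)
    lat = np.array([s.lat for s in sites])
    ids = [s.site_id for s in sites]
    base_idx = pd.MultiIndex.from_product([ids, SEASONS], names=["site_id", "season"])
    lat_per_row = np.repeat(lat, len(SEASONS))
    season_warm = np.tile(
        np.array([1.1, 0.9, 0.9, 1.0, 1.2, 1.0]), len(ids)
    )  # summers warm a bit more
    out: dict = {}
    for scen in scenarios:
        if scen not in _SCENARIO_WARMING:
            raise ValueError(f"unknown scenario {scen!r}")
        for wi, window in enumerate(future_windows):
            warm = _SCENARIO_WARMING[scen][min(wi, 2)]
            dpp_amp = _SCENARIO_DPP[scen][min(wi, 2)]
            dpp_signal = dpp_amp * (lat_per_row - 49.0) / 10.0
            temp_members = []
            for _ in range(n_temp_models):
                off = rng.normal(0.0, member_sd_t)
                noise = rng.normal(0.0, member_sd_t / 2.0, len(base_idx))
                dt = warm * season_warm + off + noise
                tbl = pd.DataFrame(
                    {
                        "site_id": base_idx.get_level_values(0),
                        "season": base_idx.get_level_values(1),
                        "dtmax": dt + 0.1,
                        "dtmin": dt - 0.1,
                        "dpp": 0.0,
                    }
                )
                temp_members.append(ScenarioDelta(scenario=scen, window=window, table=tbl))
            precip_members = []
            for _ in range(n_precip_models):
                off = rng.normal(0.0, member_sd_p)
                noise = rng.normal(0.0, member_sd_p / 2.0, len(base_idx))
                tbl = pd.DataFrame(
                    {
                        "site_id": base_idx.get_level_values(0),
                        "season": base_idx.get_level_values(1),
                        "dtmax": 0.0,
                        "dtmin": 0.0,
                        "dpp": dpp_signal + off + noise,
                    }
                )
                precip_members.append(ScenarioDelta(scenario=scen, window=window, table=tbl))
            out[(scen, window)] = (temp_members, precip_members)
    return out


# ---------------------------------------------------------------------------
# Whole networks
# ---------------------------------------------------------------------------

def generate_network(
    n_sites: int = 20,
    trees_per_site: int = 3,
    year_range: tuple[int, int] = (1950, 2016),
    climate_range: tuple[int, int] = (1901, 2016),
    truth: TrueParams | None = None,
    seed: int = 0,
    trend: float = 0.2,
) -> SyntheticNetwork:
    """End-to-end synthetic network: sites, climate, aridity, ring series."""
    rng = np.random.default_rng(seed)
    s_sites, s_clim, s_grow = rng.integers(0, 2**31 - 1, size=3)
    sites = generate_sites(n_sites, int(s_sites))
    monthly = generate_monthly_climate(sites, year_range=climate_range, trend=trend, seed=int(s_clim))
    ai = site_mean_ai(monthly, window=(max(1950, climate_range[0]), min(2016, climate_range[1])))
    for s in sites:
        s.ai = float(ai[s.site_id])
    truth = truth or default_true_params()
    rings, true_bai, scaler = simulate_growth(
        monthly,
        sites,
        truth,
        trees_per_site,
        year_range=year_range,
        seed=int(s_grow),
        return_truth=True,
    )
    return SyntheticNetwork(
        sites=sites,
        climate=monthly,
        rings=rings,
        truth=truth,
        seed=seed,
        true_bai=true_bai,
        scaler=scaler,
    )


def write_network(network: SyntheticNetwork, outdir) -> None:
    """Write rwl + metadata CSVs + monthly climate CSV + truth YAML."""
    import os

    os.makedirs(outdir, exist_ok=True)
    write_rwl(network.rings, os.path.join(outdir, "rings.rwl"))
    pd.DataFrame(
        {
            "tree_code": [r.tree_code for r in network.rings],
            "site_id": [r.site_id for r in network.rings],
            "dbh_mm": [r.dbh_mm for r in network.rings],
        }
    ).to_csv(os.path.join(outdir, "trees.csv"), index=False)
    pd.DataFrame(
        {
            "site_id": [s.site_id for s in network.sites],
            "lat": [s.lat for s in network.sites],
            "lon": [s.lon for s in network.sites],
            "alt": [s.alt for s in network.sites],
            "ai": [s.ai for s in network.sites],
        }
    ).to_csv(os.path.join(outdir, "sites.csv"), index=False)
    network.climate.to_csv(os.path.join(outdir, "climate.csv"), index=False)
    truth = network.truth
    with open(os.path.join(outdir, "truth.yaml"), "w") as fh:
        yaml.safe_dump(
            {
                "intercept": float(truth.intercept),
                "coef": {k: float(v) for k, v in truth.coef.items()},
                "re_sd_intercept": float(truth.re_sd_intercept),
                "re_sd_slope": float(truth.re_sd_slope),
                "re_corr": float(truth.re_corr),
                "gamma_shape": float(truth.gamma_shape),
                "ba_stats": [float(x) for x in truth.ba_stats],
            },
            fh,
        )
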