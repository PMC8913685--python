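"""Seasonal climate predictors, De Martonne aridity and delta-change scenarios.

Monthly site climate (tmax, tmin in deg C; prcp in mm) is aggregated to the six
meteorological seasons a ring of year *t* responds to: previous-year summer
(pSUM) and autumn (pAUT), then winter (WIN: Dec of t-1, Jan, Feb of t),
spring (SPR), summer (SUM) and autumn (AUT) of year t. Temperatures are
averaged and precipitation summed within a season.

Long-term site moisture is the De Martonne aridity index AI = P / (10 + T)
with P the annual precipitation sum (mm) and T the annual mean temperature
(deg C); higher values are wetter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SEASONS",
    "SEASON_MONTHS",
    "ARIDITY_BOUNDS",
    "ARIDITY_CLASSES",
    "SiteMeta",
    "ScenarioDelta",
    "aggregate_seasons",
    "seasonal_wide",
    "annual_summary",
    "de_martonne",
    "classify_aridity",
    "site_mean_ai",
    "ensemble_mean_delta",
    "apply_delta",
]

#: season order used everywhere downstream (previous summer -> current autumn)
SEASONS = ("pSUM", "pAUT", "WIN", "SPR", "SUM", "AUT")

#: months of each current-year season; (month, year offset) pairs for winter
SEASON_MONTHS = {
    "WIN": ((12, -1), (1, 0), (2, 0)),
    "SPR": ((3, 0), (4, 0), (5, 0)),
    "SUM": ((6, 0), (7, 0), (8, 0)),
    "AUT": ((9, 0), (10, 0), (11, 0)),
}

ARIDITY_BOUNDS = (10.0, 20.0, 24.0, 28.0, 35.0, 55.0)
ARIDITY_CLASSES = (
    "arid",
    "semi-arid",
    "Mediterranean",
    "semi-humid",
    "humid",
    "very humid",
    "extremely humid",
)


@dataclass
class SiteMeta:
    """Site geography plus its long-term De Martonne aridity index."""

    site_id: str
    lat: float  # degrees N
    lon: float  # degrees E
    alt: float  # m a.s.l.
    ai: float = np.nan  # De Martonne units, filled from climate

    def __post_init__(self) -> None:
        if self.alt < 0:
            raise ValueError(f"site {self.site_id}: altitude must be >= 0")
        if np.isfinite(self.ai) and self.ai < 0:
            raise ValueError(f"site {self.site_id}: aridity index must be >= 0")


@dataclass
class ScenarioDelta:
    """Additive seasonal climate offsets for one scenario x future window.

    ``table`` has one row per (site_id, season) with columns dtmax, dtmin
    (deg C) and dpp (mm per season).
    """

    scenario: str
    window: tuple[int, int]
    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"site_id", "season", "dtmax", "dtmin", "dpp"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"ScenarioDelta table missing columns {sorted(missing)}")
        if not np.isfinite(self.table[["dtmax", "dtmin", "dpp"]].to_numpy()).all():
            raise ValueError("ScenarioDelta values must be finite")


# ---------------------------------------------------------------------------
# Seasonal aggregation
# ---------------------------------------------------------------------------

def _season_frame(monthly: pd.DataFrame, season: str, out_season: str, year_shift: int) -> pd.DataFrame:
    """Aggregate one meteorological season, keyed to ring year + shift."""
    parts = []
    for month, offset in SEASON_MONTHS[season]:
        sub = monthly[monthly["month"] == month].copy()
        # a December with offset -1 contributes to the *following* year's winter
        sub["key_year"] = sub["year"] - offset + year_shift
        parts.append(sub)
    stack = pd.concat(parts, ignore_index=True)
    grouped = stack.groupby(["site_id", "key_year"])
    agg = grouped.agg(
        tmax_mean=("tmax", "mean"),
        tmin_mean=("tmin", "mean"),
        pp_sum=("prcp", "sum"),
        n_months=("month", "size"),
    ).reset_index()
    agg = agg[agg["n_months"] == 3].drop(columns="n_months")
    agg = agg.rename(columns={"key_year": "year"})
    agg["season"] = out_season
    return agg


def aggregate_seasons(monthly: pd.DataFrame) -> pd.DataFrame:
    """Monthly (site_id, year, month, tmax, tmin, prcp) -> seasonal table.

    Emits rows (site_id, year, season, tmax_mean, tmin_mean, pp_sum) for the
    six seasons relevant to the ring formed in ``year``; seasons with missing
    months are omitted.
    """
    if monthly.empty:
        raise ValueError("empty monthly climate table")
    bad = monthly["tmin"] > monthly["tmax"] + 1e-9
    if bad.any():
        raise ValueError("tmin exceeds tmax in monthly climate input")
    if (monthly["prcp"] < 0).any():
        raise ValueError("negative precipitation in monthly climate input")
    parts = [
        _season_frame(monthly, "SUM", "pSUM", 1),
        _season_frame(monthly, "AUT", "pAUT", 1),
        _season_frame(monthly, "WIN", "WIN", 0),
        _season_frame(monthly, "SPR", "SPR", 0),
        _season_frame(monthly, "SUM", "SUM", 0),
        _season_frame(monthly, "AUT", "AUT", 0),
    ]
    out = pd.concat(parts, ignore_index=True)
    out["season"] = pd.Categorical(out["season"], categories=list(SEASONS), ordered=True)
    return out.sort_values(["site_id", "year", "season"]).reset_index(drop=True)


def seasonal_wide(seasonal: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long seasonal table to one row per (site_id, year).

    Columns are named ``tmax_pSUM`` ... ``pp_AUT``; only complete years (all
    six seasons present) are retained.
    """
    piv = seasonal.pivot_table(
        index=["site_id", "year"],
        columns="season",
        values=["tmax_mean", "tmin_mean", "pp_sum"],
        observed=True,
    )
    piv.columns = [
        f"{ {'tmax_mean': 'tmax', 'tmin_mean': 'tmin', 'pp_sum': 'pp'}[v] }_{s}"
        for v, s in piv.columns
    ]
    piv = piv.dropna()
    return piv.reset_index()


def annual_summary(monthly: pd.DataFrame) -> pd.DataFrame:
    """Per (site, calendar year): annual precipitation sum and mean temperature.

    The mean temperature is the mean of the monthly midpoints (tmax+tmin)/2.
    """
    m = monthly.copy()
    m["tmid"] = 0.5 * (m["tmax"] + m["tmin"])
    agg = (
        m.groupby(["site_id", "year"])
        .agg(p_annual=("prcp", "sum"), t_annual=("tmid", "mean"), n=("month", "size"))
        .reset_index()
    )
    agg = agg[agg["n"] == 12].drop(columns="n")
    return agg


# ---------------------------------------------------------------------------
# De Martonne aridity
# ---------------------------------------------------------------------------

def de_martonne(p_annual, t_annual):
    """De Martonne aridity index ``AI = P / (10 + T)``.

    ``P`` in mm/yr, ``T`` in deg C; undefined at and below T = -10 deg C.
    """
    p = np.asarray(p_annual, dtype=float)
    t = np.asarray(t_annual, dtype=float)
    if np.any(t <= -10.0):
        raise ValueError("De Martonne index undefined for T <= -10 deg C")
    out = p / (10.0 + t)
    return float(out) if out.ndim == 0 else out


def classify_aridity(ai) -> str | np.ndarray:
    """Map an aridity index to its De Martonne climate class.

    Classes are lower-inclusive half-open intervals with bounds
    10, 20, 24, 28, 35, 55; values >= 55 are "extremely humid".
    """
    arr = np.asarray(ai, dtype=float)
    if np.any(arr < 0):
        raise ValueError("aridity index must be >= 0")
    idx = np.searchsorted(ARIDITY_BOUNDS, arr, side="right")
    out = np.asarray(ARIDITY_CLASSES, dtype=object)[idx]
    return str(out) if arr.ndim == 0 else out


def site_mean_ai(monthly: pd.DataFrame, window: tuple[int, int] = (1950, 2016)) -> pd.Series:
    """Long-term site aridity: mean of annual AI values over ``window`` (inclusive)."""
    lo, hi = window
    if lo > hi:
        raise ValueError(f"empty aridity window {window}")
    ann = annual_summary(monthly)
    ann = ann[(ann["year"] >= lo) & (ann["year"] <= hi)]
    if ann.empty:
        raise ValueError(f"no complete climate years inside window {window}")
    ann = ann.assign(ai=de_martonne(ann["p_annual"], ann["t_annual"]))
    return ann.groupby("site_id")["ai"].mean()


# ---------------------------------------------------------------------------
# Delta-change scenarios
# ---------------------------------------------------------------------------

def _check_alignment(members: list[pd.DataFrame]) -> None:
    ref = members[0].set_index(["site_id", "season"]).index
    for i, m in enumerate(members[1:], start=2):
        idx = m.set_index(["site_id", "season"]).index
        if len(idx) != len(ref) or not idx.sort_values().equals(ref.sort_values()):
            raise ValueError(f"ensemble member {i} is on a mismatched (site, season) set")


def ensemble_mean_delta(
    temp_members: list[ScenarioDelta],
    precip_members: list[ScenarioDelta],
) -> ScenarioDelta:
    """Average per-model climate deltas into one ensemble-mean delta set.

    Temperature (dtmax, dtmin) and precipitation (dpp) ensembles are averaged
    separately — their member counts may differ (e.g. 21 vs 26 models).
    """
    if not temp_members or not precip_members:
        raise ValueError("need at least one member per variable ensemble")
    _check_alignment([m.table for m in temp_members] + [m.table for m in precip_members])
    scenario = temp_members[0].scenario
    window = temp_members[0].window
    key = ["site_id", "season"]
    t_stack = pd.concat([m.table[key + ["dtmax", "dtmin"]] for m in temp_members])
    p_stack = pd.concat([m.table[key + ["dpp"]] for m in precip_members])
    t_mean = t_stack.groupby(key, observed=True).mean().reset_index()
    p_mean = p_stack.groupby(key, observed=True).mean().reset_index()
    table = t_mean.merge(p_mean, on=key, validate="one_to_one")
    return ScenarioDelta(scenario=scenario, window=window, table=table)


def apply_delta(seasonal: pd.DataFrame, delta: ScenarioDelta) -> pd.DataFrame:
    """Shift a seasonal climate table by additive deltas.

    Temperatures shift by dtmax/dtmin; seasonal precipitation by dpp, floored
    at zero. Geography and the long-term aridity index are untouched by
    construction (they are not part of the seasonal table).
    """
    merged = seasonal.merge(delta.table, on=["site_id", "season"], how="left")
    if merged[["dtmax", "dtmin", "dpp"]].isna().any().any():
        raise ValueError("delta table does not cover every (site, season) of the baseline")
    out = seasonal.copy()
    out["tmax_mean"] = (merged["tmax_mean"] + merged["dtmax"]).to_numpy()
    out["tmin_mean"] = (merged["tmin_mean"] + merged["dtmin"]).to_numpy()
    out["pp_sum"] = np.clip((merged["pp_sum"] + merged["dpp"]).to_numpy(), 0.0, None)
    return out
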