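"""Grid application of the fitted growth model: period means, percent change
and applicability-domain masking.

Predictions are made for a population-average reference tree at a fixed basal
area (default 86059.03 mm^2, roughly an 80-year-old beech) so that maps of
different periods compare climate response, not tree size. Pixels whose
scenario climate leaves the range of the training climate (the model's
applicability domain) are flagged, not dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .climate import ScenarioDelta, SiteMeta, apply_delta, seasonal_wide
from .model import FittedGrowthModel, predict_bai

__all__ = [
    "REFERENCE_BA",
    "PredictionGrid",
    "ADMask",
    "ScenarioResult",
    "predict_grid",
    "period_mean",
    "percent_change",
    "applicability_domain",
    "run_scenarios",
    "DEFAULT_SCENARIOS",
    "DEFAULT_FUTURE_WINDOWS",
]

#: reference basal area of the population-average tree, mm^2
REFERENCE_BA = 86059.03

DEFAULT_SCENARIOS = ("SSP1-2.6", "SSP5-8.5")
DEFAULT_FUTURE_WINDOWS = ((2020, 2050), (2040, 2070), (2060, 2090))

_AD_VARS = {"tmax_mean": "tmax", "tmin_mean": "tmin", "pp_sum": "pp"}


@dataclass
class PredictionGrid:
    """Annual population-level BAI predictions per pixel at fixed basal area."""

    table: pd.DataFrame  # columns: site_id, year, bai
    ba_fixed: float

    def __post_init__(self) -> None:
        if (self.table["bai"] <= 0).any():
            raise ValueError("predicted BAI must be strictly positive")


@dataclass
class ADMask:
    """Per-pixel applicability-domain flag with enumerated range violations."""

    inside: pd.Series  # index site_id -> bool
    violations: dict[str, list[tuple[str, str, str]]]  # site_id -> (var, season, direction)

    def __post_init__(self) -> None:
        for pix, ok in self.inside.items():
            if ok != (len(self.violations.get(pix, [])) == 0):
                raise ValueError(f"inconsistent AD mask for pixel {pix}")

    @property
    def fraction_inside(self) -> float:
        return float(self.inside.mean())


@dataclass
class ScenarioResult:
    scenario: str
    window: tuple[int, int]
    change_map: pd.DataFrame  # site_id, mean_a, mean_b, pct_change
    ad_mask: ADMask = field(repr=False, default=None)


def predict_grid(
    model: FittedGrowthModel,
    grid_seasonal: pd.DataFrame,
    grid_meta: list[SiteMeta],
    ba_fixed: float = REFERENCE_BA,
) -> PredictionGrid:
    """Population-level annual BAI per pixel-year at a constant basal area."""
    meta_df = pd.DataFrame(
        {"site_id": [s.site_id for s in grid_meta], "lat": [s.lat for s in grid_meta],
         "alt": [s.alt for s in grid_meta], "ai": [s.ai for s in grid_meta]}
    )
    wide = seasonal_wide(grid_seasonal)
    frame = wide.merge(meta_df, on="site_id", how="left", validate="many_to_one")
    if frame["lat"].isna().any():
        missing = sorted(frame.loc[frame["lat"].isna(), "site_id"].unique())
        raise ValueError(f"grid pixels missing metadata: {missing[:5]}")
    bai = predict_bai(model, frame, ba_fixed=ba_fixed, population_level=True)
    table = pd.DataFrame({"site_id": frame["site_id"], "year": frame["year"], "bai": bai})
    return PredictionGrid(table=table, ba_fixed=ba_fixed)


def period_mean(grid: PredictionGrid, window: tuple[int, int]) -> pd.Series:
    """Per-pixel mean BAI over an inclusive year window (all years required)."""
    lo, hi = window
    if lo > hi:
        raise ValueError(f"empty window {window}")
    want = set(range(lo, hi + 1))
    sub = grid.table[(grid.table["year"] >= lo) & (grid.table["year"] <= hi)]
    by_pix = sub.groupby("site_id")["year"].apply(lambda s: want - set(s))
    missing = {pix: sorted(m) for pix, m in by_pix.items() if m}
    if missing or sub.empty:
        example = next(iter(missing.items())) if missing else ("all pixels", sorted(want))
        raise ValueError(f"window {window} not fully covered; missing years e.g. {example}")
    return sub.groupby("site_id")["bai"].mean()


def percent_change(mean_a, mean_b):
    """Percent change of b relative to a: ``100 (b - a) / a``."""
    a = np.asarray(mean_a, dtype=float)
    b = np.asarray(mean_b, dtype=float)
    if np.any(a <= 0):
        raise ValueError("reference period mean must be > 0")
    out = 100.0 * (b - a) / a
    return float(out) if out.ndim == 0 else out


def applicability_domain(
    training_seasonal: pd.DataFrame,
    future_seasonal: pd.DataFrame,
) -> ADMask:
    """Range check of future seasonal climate against the training domain.

    Training min/max are pooled per (variable, season) over all sites and
    years of the training table; a pixel is outside the applicability domain
    if any of its future values exceeds those bounds in either direction.
    """
    if training_seasonal.empty:
        raise ValueError("empty training climate")
    ranges = (
        training_seasonal.groupby("season", observed=True)[list(_AD_VARS)]
        .agg(["min", "max"])
    )
    violations: dict[str, list[tuple[str, str, str]]] = {}
    pixels = pd.unique(future_seasonal["site_id"])
    fut = future_seasonal.groupby(["site_id", "season"], observed=True)[list(_AD_VARS)].agg(
        ["min", "max"]
    )
    for (pix, season), row in fut.iterrows():
        for col, short in _AD_VARS.items():
            lo = ranges.loc[season, (col, "min")]
            hi = ranges.loc[season, (col, "max")]
            if row[(col, "min")] < lo:
                violations.setdefault(pix, []).append((short, str(season), "below"))
            if row[(col, "max")] > hi:
                violations.setdefault(pix, []).append((short, str(season), "above"))
    inside = pd.Series({pix: pix not in violations for pix in pixels}, name="inside")
    return ADMask(inside=inside, violations=violations)


def run_scenarios(
    model: FittedGrowthModel,
    baseline_seasonal: pd.DataFrame,
    grid_meta: list[SiteMeta],
    deltas: dict[tuple[str, tuple[int, int]], ScenarioDelta],
    training_seasonal: pd.DataFrame | None = None,
    ba_fixed: float = REFERENCE_BA,
    baseline_window: tuple[int, int] = (1986, 2016),
    scenarios: tuple[str, ...] = DEFAULT_SCENARIOS,
    future_windows: tuple[tuple[int, int], ...] = DEFAULT_FUTURE_WINDOWS,
) -> list[ScenarioResult]:
    """Project growth change for every scenario x future window combination.

    For each combination: shift the baseline-period seasonal climate by the
    ensemble-mean delta, predict the reference tree's annual BAI, average
    over the (delta-shifted) baseline years, and express the change relative
    to the unshifted baseline period mean. Interannual variability of the
    baseline period is thereby preserved under the shift. An AD mask against
    the training climate is attached when ``training_seasonal`` is given.
    """
    wanted = [(s, w) for s in scenarios for w in future_windows]
    missing = [k for k in wanted if k not in deltas]
    if missing:
        raise ValueError(f"missing delta sets for {missing}")
    base = baseline_seasonal[
        (baseline_seasonal["year"] >= baseline_window[0] - 1)
        & (baseline_seasonal["year"] <= baseline_window[1])
    ]
    base_grid = predict_grid(model, base, grid_meta, ba_fixed=ba_fixed)
    base_mean = period_mean(base_grid, baseline_window)
    results = []
    for key in wanted:
        delta = deltas[key]
        shifted = apply_delta(base, delta)
        grid = predict_grid(model, shifted, grid_meta, ba_fixed=ba_fixed)
        fut_mean = period_mean(grid, baseline_window)
        fut_mean = fut_mean.reindex(base_mean.index)
        change = pd.DataFrame(
            {
                "site_id": base_mean.index,
                "mean_a": base_mean.to_numpy(),
                "mean_b": fut_mean.to_numpy(),
                "pct_change": percent_change(base_mean.to_numpy(), fut_mean.to_numpy()),
            }
        )
        mask = (
            applicability_domain(training_seasonal, shifted)
            if training_seasonal is not None
            else None
        )
        results.append(
            ScenarioResult(scenario=key[0], window=key[1], change_map=change, ad_mask=mask)
        )
    return results
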