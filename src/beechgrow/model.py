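"""Gamma log-link mixed growth model: design construction, Laplace ML fit,
nested-model comparison and prediction.

The model predicts annual basal area increment (BAI, mm^2/yr) of tree *j* at
site *i* in year *t* from long-term aridity, geography and seasonal climate::

    log E[BAI_ijt] = beta0 + log(AI_i) + f(LAT_i) + f(ALT_i)
                     + sum_k [ f(Tmax_itk) + f(Tmin_itk) + log(PP_itk) ]
                     + interactions{AI x geo, geo x geo, (AI, LAT, ALT) x climate}
                     + b0_j + b1_j * BA_ijt
    BAI_ijt ~ Gamma(shape, mean = E[BAI_ijt])
    (b0_j, b1_j) ~ N(0, Sigma)   per tree

with f(.) a quadratic polynomial basis on the standardized variable, log
transforms for aridity and precipitation, and a per-tree correlated random
intercept and random slope on previous-year basal area (BA). The random BA
slope absorbs tree-level size/age trends so period means are comparable
without classical detrending.

Fitting maximizes the Laplace-approximated marginal likelihood: for candidate
variance/dispersion parameters, the penalized conditional mode of (beta, b)
is found by a damped Newton iteration exploiting the per-tree block structure
(a Schur complement over 2x2 blocks), and the profiled Laplace objective is
optimized over the random-effect covariance (log-Cholesky scale) and the
gamma shape by Nelder-Mead. An adaptive Gauss-Hermite evaluation of the
marginal likelihood is available for accuracy checks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg, optimize, special, stats

from .climate import SEASONS, SiteMeta, seasonal_wide

__all__ = [
    "ModelSpec",
    "Scaler",
    "DesignMatrix",
    "FittedGrowthModel",
    "build_design",
    "build_covariate_frame",
    "compute_scaler",
    "design_from_frame",
    "fit_glmm",
    "marginal_loglik_agq",
    "compare_models",
    "default_ladder",
    "predict_bai",
]

ETA_CLIP = 35.0  # linear-predictor clamp guarding exp overflow during line search


# ---------------------------------------------------------------------------
# Model specification and variable vocabulary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Vocabulary, transforms and structure of the growth model design.

    Defaults give the canonical 21-main-variable model: AI, LAT, ALT plus
    Tmax/Tmin/PP over the six seasons from previous-year summer to
    current-year autumn.
    """

    seasons: tuple[str, ...] = SEASONS
    climate_vars: tuple[str, ...] = ("tmax", "tmin", "pp")
    basis_df: int = 2
    interaction_mode: str = "linear"  # "linear" | "expanded" | "none"
    interaction_blocks: tuple[str, ...] = (
        "ai_geo",
        "geo_geo",
        "ai_cli",
        "lat_cli",
        "alt_cli",
    )
    pp_offset: float = 1.0  # mm, guards log of zero seasonal precipitation
    include_ba_fixed: bool = True

    def __post_init__(self) -> None:
        if self.basis_df < 1:
            raise ValueError("basis_df must be >= 1")
        if self.interaction_mode not in ("linear", "expanded", "none"):
            raise ValueError(f"unknown interaction_mode {self.interaction_mode!r}")
        unknown = set(self.interaction_blocks) - {"ai_geo", "geo_geo", "ai_cli", "lat_cli", "alt_cli"}
        if unknown:
            raise ValueError(f"unknown interaction blocks {sorted(unknown)}")

    @property
    def main_variables(self) -> tuple[str, ...]:
        clim = tuple(f"{v}_{s}" for v in self.climate_vars for s in self.seasons)
        return ("ai", "lat", "alt") + clim

    @property
    def n_main_variables(self) -> int:
        return len(self.main_variables)

    def variable_group(self, name: str) -> str:
        if name == "ai":
            return "ai"
        if name in ("lat", "alt"):
            return "geo"
        return "cli"

    def is_smooth(self, name: str) -> bool:
        """Variables entering through the polynomial basis f(.)."""
        return name in ("lat", "alt") or name.startswith(("tmax_", "tmin_"))

    def is_logged(self, name: str) -> bool:
        return name == "ai" or name.startswith("pp_")

    def expanded_names(self, name: str) -> list[str]:
        if self.is_smooth(name) and self.basis_df > 1:
            return [f"{name}^{k}" for k in range(1, self.basis_df + 1)]
        return [name]

    def interaction_pairs(self) -> list[tuple[str, str]]:
        """(left, right) variable pairs of the declared interaction blocks."""
        clim = [v for v in self.main_variables if self.variable_group(v) == "cli"]
        pairs: list[tuple[str, str]] = []
        if "ai_geo" in self.interaction_blocks:
            pairs += [("ai", "lat"), ("ai", "alt")]
        if "geo_geo" in self.interaction_blocks:
            pairs += [("lat", "alt")]
        if "ai_cli" in self.interaction_blocks:
            pairs += [("ai", c) for c in clim]
        if "lat_cli" in self.interaction_blocks:
            pairs += [("lat", c) for c in clim]
        if "alt_cli" in self.interaction_blocks:
            pairs += [("alt", c) for c in clim]
        return pairs

    def n_fixed_columns(self) -> int:
        """Closed-form fixed-effect column count (including the intercept)."""
        n = 1  # intercept
        for v in self.main_variables:
            n += len(self.expanded_names(v))
        if self.interaction_mode == "linear":
            n += len(self.interaction_pairs())
        elif self.interaction_mode == "expanded":
            for a, b in self.interaction_pairs():
                n += len(self.expanded_names(a)) * len(self.expanded_names(b))
        if self.include_ba_fixed:
            n += 1
        return n


@dataclass
class Scaler:
    """Standardization state: per-variable stats after transforms, then
    per-column stats of the expanded design. Stored with the fit so grids and
    scenarios are transformed identically to the training data."""

    var_stats: dict[str, tuple[float, float]]
    col_stats: dict[str, tuple[float, float]]


@dataclass
class DesignMatrix:
    """Response, fixed-effect matrix and per-tree random-effect structure."""

    y: np.ndarray | None
    X: np.ndarray
    col_names: list[str]
    col_groups: list[frozenset]
    z_ba: np.ndarray
    group_idx: np.ndarray
    group_labels: list[str]
    scaler: Scaler
    spec: ModelSpec
    meta: pd.DataFrame

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)

    def subset_groups(self, groups: tuple[str, ...]) -> "DesignMatrix":
        """Keep fixed columns whose parent groups are all in ``groups``.

        The intercept and the BA column (empty group set) are always kept —
        the null model retains the intercept and the random structure.
        """
        keep = [i for i, g in enumerate(self.col_groups) if g <= set(groups)]
        return replace(
            self,
            X=self.X[:, keep],
            col_names=[self.col_names[i] for i in keep],
            col_groups=[self.col_groups[i] for i in keep],
        )


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def build_covariate_frame(
    bai_table: pd.DataFrame,
    seasonal: pd.DataFrame,
    sites: list[SiteMeta],
    spec: ModelSpec,
) -> pd.DataFrame:
    """Join BAI rows with seasonal climate and site geography/aridity.

    Output has one row per (tree, year) with raw covariates ``ai, lat, alt,
    tmax_pSUM, ..., pp_AUT`` plus ``bai``, ``ba_prev`` and identifiers.
    """
    site_df = pd.DataFrame(
        {"site_id": [s.site_id for s in sites], "lat": [s.lat for s in sites],
         "alt": [s.alt for s in sites], "ai": [s.ai for s in sites]}
    )
    if site_df["ai"].isna().any():
        raise ValueError("every site needs a long-term aridity index (ai)")
    wide = seasonal_wide(seasonal)
    merged = bai_table.merge(site_df, on="site_id", how="left", validate="many_to_one")
    if merged["lat"].isna().any():
        missing = sorted(merged.loc[merged["lat"].isna(), "site_id"].unique())
        raise ValueError(f"sites missing from metadata: {missing[:5]}")
    merged = merged.merge(wide, on=["site_id", "year"], how="left", validate="many_to_one")
    needed = [c for c in wide.columns if c not in ("site_id", "year")]
    if merged[needed].isna().any().any():
        bad = merged.loc[merged[needed].isna().any(axis=1), ["site_id", "year"]]
        raise ValueError(
            f"incomplete seasonal climate for {len(bad)} (site, year) rows, "
            f"e.g. {bad.iloc[0].tolist()}"
        )
    return merged


def _stage1(frame: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Apply the log transforms of the model formula (before standardization)."""
    out = pd.DataFrame(index=frame.index)
    for v in spec.main_variables:
        x = frame[v].to_numpy(dtype=float)
        if spec.is_logged(v):
            offset = spec.pp_offset if v.startswith("pp_") else 0.0
            if np.any(x + offset <= 0):
                raise ValueError(
                    f"variable {v}: log transform undefined at <= 0; "
                    f"increase pp_offset in the ModelSpec" if v.startswith("pp_")
                    else f"variable {v}: log transform undefined at <= 0"
                )
            x = np.log(x + offset)
        out[v] = x
    return out


def _zscore_frame(t_frame: pd.DataFrame, var_stats: dict) -> pd.DataFrame:
    z = pd.DataFrame(index=t_frame.index)
    for v in t_frame.columns:
        m, s = var_stats[v]
        z[v] = (t_frame[v] - m) / s
    return z


def _expand(z_frame: pd.DataFrame, spec: ModelSpec):
    """Basis-expand standardized mains and form interaction columns.

    Returns (matrix, names, groups) excluding intercept and BA column.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    groups: list[frozenset] = []
    expanded: dict[str, list[tuple[str, np.ndarray]]] = {}
    for v in spec.main_variables:
        z = z_frame[v].to_numpy()
        ex = []
        for k, nm in enumerate(spec.expanded_names(v), start=1):
            ex.append((nm, z**k))
        expanded[v] = ex
        for nm, c in ex:
            cols.append(c)
            names.append(nm)
            groups.append(frozenset([spec.variable_group(v)]))
    if spec.interaction_mode != "none":
        for a, b in spec.interaction_pairs():
            grp = frozenset([spec.variable_group(a), spec.variable_group(b)])
            if spec.interaction_mode == "linear":
                cols.append(z_frame[a].to_numpy() * z_frame[b].to_numpy())
                names.append(f"{a}:{b}")
                groups.append(grp)
            else:
                for na, ca in expanded[a]:
                    for nb, cb in expanded[b]:
                        cols.append(ca * cb)
                        names.append(f"{na}:{nb}")
                        groups.append(grp)
    return np.column_stack(cols), names, groups


def _var_stats_from(t_frame: pd.DataFrame) -> dict:
    stats_: dict[str, tuple[float, float]] = {}
    for v in t_frame.columns:
        x = t_frame[v].to_numpy(dtype=float)
        m, s = float(x.mean()), float(x.std())
        if s < 1e-12:
            raise ValueError(f"standardization error: variable {v!r} is constant in the training data")
        stats_[v] = (m, s)
    return stats_


def compute_scaler(
    frame: pd.DataFrame,
    spec: ModelSpec,
    ba_stats: tuple[float, float] | None = None,
) -> Scaler:
    """Standardization state from a covariate frame.

    ``ba_stats`` fixes the (mean, sd) used for previous basal area — needed
    when the scaler must be defined before growth (hence BA) is realized, as
    in forward simulation; otherwise BA stats come from ``frame['ba_prev']``.
    """
    t_frame = _stage1(frame, spec)
    var_stats = _var_stats_from(t_frame)
    if ba_stats is not None:
        var_stats["ba_prev"] = (float(ba_stats[0]), float(ba_stats[1]))
    elif "ba_prev" in frame.columns:
        x = frame["ba_prev"].to_numpy(dtype=float)
        if x.std() < 1e-12:
            raise ValueError("standardization error: variable 'ba_prev' is constant")
        var_stats["ba_prev"] = (float(x.mean()), float(x.std()))
    else:
        raise ValueError("frame lacks ba_prev and no ba_stats supplied")
    z = _zscore_frame(t_frame, var_stats)
    M, names, _ = _expand(z, spec)
    col_stats: dict[str, tuple[float, float]] = {}
    for j, nm in enumerate(names):
        m, s = float(M[:, j].mean()), float(M[:, j].std())
        if s < 1e-12:
            raise ValueError(f"standardization error: design column {nm!r} is constant")
        col_stats[nm] = (m, s)
    return Scaler(var_stats=var_stats, col_stats=col_stats)


def design_from_frame(
    frame: pd.DataFrame,
    spec: ModelSpec,
    scaler: Scaler,
    with_response: bool = True,
) -> DesignMatrix:
    """Assemble the fixed-effect matrix (and response) from a covariate frame
    using a pre-computed scaler. Column order: intercept, expanded mains,
    interactions, BA."""
    t_frame = _stage1(frame, spec)
    for v in spec.main_variables:
        if v not in scaler.var_stats:
            raise ValueError(f"variable {v!r} outside the scaler vocabulary")
    z = _zscore_frame(t_frame, scaler.var_stats)
    M, names, groups = _expand(z, spec)
    for j, nm in enumerate(names):
        m, s = scaler.col_stats[nm]
        M[:, j] = (M[:, j] - m) / s
    n = len(frame)
    mba, sba = scaler.var_stats["ba_prev"]
    if "ba_prev" in frame.columns:
        z_ba = (frame["ba_prev"].to_numpy(dtype=float) - mba) / sba
    else:
        z_ba = np.zeros(n)
    parts = [np.ones((n, 1)), M]
    all_names = ["(Intercept)"] + names
    all_groups = [frozenset()] + groups
    if spec.include_ba_fixed:
        parts.append(z_ba[:, None])
        all_names.append("ba_prev")
        all_groups.append(frozenset())
    X = np.hstack(parts)
    if with_response:
        y = frame["bai"].to_numpy(dtype=float)
        if np.any(y <= 0):
            raise ValueError("gamma response requires strictly positive BAI")
    else:
        y = None
    if "tree_code" in frame.columns:
        codes, labels = pd.factorize(frame["tree_code"], sort=True)
    else:
        codes, labels = np.zeros(n, dtype=int), pd.Index(["_pop"])
    meta_cols = [c for c in ("site_id", "tree_code", "year") if c in frame.columns]
    return DesignMatrix(
        y=y,
        X=X,
        col_names=all_names,
        col_groups=all_groups,
        z_ba=z_ba,
        group_idx=np.asarray(codes, dtype=int),
        group_labels=list(labels),
        scaler=scaler,
        spec=spec,
        meta=frame[meta_cols].copy(),
    )


def build_design(
    bai_table: pd.DataFrame,
    seasonal: pd.DataFrame,
    sites: list[SiteMeta],
    spec: ModelSpec | None = None,
    scaler: Scaler | None = None,
) -> DesignMatrix:
    """Standardized model design from a BAI table, seasonal climate and sites.

    Transforms are applied in order log -> standardize -> basis expansion,
    then every expanded column is itself standardized; the scaler is stored
    for reuse at prediction time. Passing ``scaler`` reuses an existing
    standardization (e.g. the generating one in simulation studies).
    """
    spec = spec or ModelSpec()
    frame = build_covariate_frame(bai_table, seasonal, sites, spec)
    if scaler is None:
        scaler = compute_scaler(frame, spec)
    return design_from_frame(frame, spec, scaler, with_response=True)


# ---------------------------------------------------------------------------
# Laplace-approximated maximum likelihood
# ---------------------------------------------------------------------------

def _chol_from_theta(theta: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor of the RE covariance from (log s1, log s2, c)."""
    a, b, c = theta
    return np.array([[math.exp(a), 0.0], [c, math.exp(b)]])


def _gamma_loglik_sum(y: np.ndarray, eta: np.ndarray, alpha: float) -> float:
    """Sum of gamma log-densities with mean exp(eta) and shape alpha."""
    return float(
        y.size * (alpha * math.log(alpha) - special.gammaln(alpha))
        + (alpha - 1.0) * np.log(y).sum()
        - alpha * (eta + y * np.exp(-eta)).sum()
    )


class _GroupedData:
    """Design arrays sorted by group, with cached Fisher cross-products.

    For the gamma family with log link the expected-information weights are
    constant (the shape), so X'X, the per-group sums of X and X*z, and the
    per-group 2x2 moment blocks fully determine the Fisher Newton system —
    they are computed once per dataset.
    """

    def __init__(self, design: DesignMatrix):
        order = np.argsort(design.group_idx, kind="stable")
        self.order = order
        self.y = design.y[order]
        self.X = np.ascontiguousarray(design.X[order])
        self.zba = design.z_ba[order]
        g = design.group_idx[order]
        self.G = design.n_groups
        self.starts = np.searchsorted(g, np.arange(self.G))
        self.g = g
        self.logy_sum = float(np.log(self.y).sum())
        # Fisher caches
        self.C0 = self.X.T @ self.X
        self.B0 = np.stack(
            [self.gsum_rows(self.X), self.gsum_rows(self.X * self.zba[:, None])], axis=2
        )  # (G, p, 2)
        self.M = np.empty((self.G, 2, 2))
        self.M[:, 0, 0] = self.gsum(np.ones_like(self.zba))
        self.M[:, 0, 1] = self.M[:, 1, 0] = self.gsum(self.zba)
        self.M[:, 1, 1] = self.gsum(self.zba**2)

    def gsum(self, v: np.ndarray) -> np.ndarray:
        return np.add.reduceat(v, self.starts)

    def gsum_rows(self, m: np.ndarray) -> np.ndarray:
        return np.add.reduceat(m, self.starts, axis=0)


def _joint_obj(gd: _GroupedData, beta, b, Sinv, alpha) -> float:
    eta = np.clip(gd.X @ beta + b[gd.g, 0] + b[gd.g, 1] * gd.zba, -ETA_CLIP, ETA_CLIP)
    data = -alpha * (eta + gd.y * np.exp(-eta)).sum()
    pen = -0.5 * np.einsum("ga,ab,gb->", b, Sinv, b)
    return float(data + pen)


def _solve_spd(S, rhs_mat):
    """Solve with an SPD matrix, escalating a ridge jitter when the Cholesky
    factorization fails or the system is numerically singular (near-collinear
    designs at small site counts)."""
    scale = float(np.mean(np.diag(S)))
    for jitter in (0.0, 1e-10, 1e-8, 1e-6, 1e-4):
        try:
            cf = linalg.cho_factor(S + jitter * scale * np.eye(S.shape[0]), lower=True)
            return linalg.cho_solve(cf, rhs_mat), cf
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("fixed-effect system not positive definite")


def _inv2x2(A: np.ndarray) -> np.ndarray:
    det = A[:, 0, 0] * A[:, 1, 1] - A[:, 0, 1] ** 2
    Ainv = np.empty_like(A)
    Ainv[:, 0, 0] = A[:, 1, 1] / det
    Ainv[:, 1, 1] = A[:, 0, 0] / det
    Ainv[:, 0, 1] = Ainv[:, 1, 0] = -A[:, 0, 1] / det
    return Ainv


def _curvature_obs(gd: _GroupedData, Sinv, alpha, beta, b) -> np.ndarray:
    """Observed per-group 2x2 curvature blocks at (beta, b) — the Hessian
    entering the Laplace determinant."""
    eta = np.clip(gd.X @ beta + b[gd.g, 0] + b[gd.g, 1] * gd.zba, -ETA_CLIP, ETA_CLIP)
    w = alpha * gd.y * np.exp(-eta)
    A = np.empty((gd.G, 2, 2))
    A[:, 0, 0] = gd.gsum(w) + Sinv[0, 0]
    A[:, 0, 1] = A[:, 1, 0] = gd.gsum(w * gd.zba) + Sinv[0, 1]
    A[:, 1, 1] = gd.gsum(w * gd.zba**2) + Sinv[1, 1]
    return A


def _pirls(gd: _GroupedData, Sinv, alpha, beta, b, tol=1e-9, max_iter=200):
    """Damped Fisher-scoring Newton for the penalized conditional mode of
    (beta, b), using the cached constant-weight system.

    Returns (beta, b, converged).
    """
    f0 = _joint_obj(gd, beta, b, Sinv, alpha)
    converged = False
    A = alpha * gd.M + Sinv[None, :, :]
    Ainv = _inv2x2(A)
    S = alpha * gd.C0 - alpha**2 * np.einsum("gpa,gab,gqb->pq", gd.B0, Ainv, gd.B0)
    scale = float(np.mean(np.diag(S)))
    S_cf = None
    for jitter in (0.0, 1e-10, 1e-8, 1e-6):
        try:
            S_cf = linalg.cho_factor(S + jitter * scale * np.eye(S.shape[0]), lower=True)
            break
        except np.linalg.LinAlgError:
            continue
    if S_cf is None:
        raise np.linalg.LinAlgError("fixed-effect Fisher system not positive definite")
    for _ in range(max_iter):
        eta = np.clip(gd.X @ beta + b[gd.g, 0] + b[gd.g, 1] * gd.zba, -ETA_CLIP, ETA_CLIP)
        mu = np.exp(eta)
        r = alpha * (gd.y - mu) / mu
        gbeta = gd.X.T @ r
        gb = np.column_stack([gd.gsum(r), gd.gsum(r * gd.zba)]) - b @ Sinv
        rhs = gbeta - alpha * np.einsum("gpa,gab,gb->p", gd.B0, Ainv, gb)
        dbeta = linalg.cho_solve(S_cf, rhs)
        db = np.einsum("gab,gb->ga", Ainv, gb - alpha * np.einsum("gpa,p->ga", gd.B0, dbeta))
        big = max(np.abs(dbeta).max(), np.abs(db).max())
        if big > 100.0:  # trust region on the standardized scale
            dbeta *= 100.0 / big
            db *= 100.0 / big
        step = 1.0
        f1 = f0
        while step > 1e-8:
            f1 = _joint_obj(gd, beta + step * dbeta, b + step * db, Sinv, alpha)
            if f1 > f0:
                break
            step *= 0.5
        if f1 <= f0:
            converged = np.abs(gbeta).max() + np.abs(gb).max() < 1e-4 * (1.0 + abs(f0))
            break
        beta = beta + step * dbeta
        b = b + step * db
        df = f1 - f0
        f0 = f1
        grad_norm = max(np.abs(gbeta).max(), np.abs(gb).max())
        if grad_norm < 1e-6 * (1.0 + abs(f0)) or step * big < tol or df < 1e-11 * (1.0 + abs(f0)):
            converged = True
            break
    return beta, b, converged


def _laplace_loglik(gd: _GroupedData, beta, b, A, Sinv, alpha, logdet_sigma) -> float:
    eta = np.clip(gd.X @ beta + b[gd.g, 0] + b[gd.g, 1] * gd.zba, -ETA_CLIP, ETA_CLIP)
    ll = _gamma_loglik_sum(gd.y, eta, alpha)
    ll -= 0.5 * np.einsum("ga,ab,gb->", b, Sinv, b)
    ll -= 0.5 * gd.G * logdet_sigma
    det = A[:, 0, 0] * A[:, 1, 1] - A[:, 0, 1] ** 2
    ll -= 0.5 * np.log(det).sum()
    return float(ll)


@dataclass
class FittedGrowthModel:
    """Maximum-likelihood fit of the gamma growth GLMM."""

    spec: ModelSpec
    scaler: Scaler
    col_names: list[str]
    col_groups: list[frozenset]
    beta: np.ndarray
    se: np.ndarray
    re_cov: np.ndarray  # 2x2: (intercept, BA slope)
    gamma_shape: float
    loglik: float
    n_obs: int
    n_groups: int
    blups: pd.DataFrame = field(repr=False, default=None)
    converged: bool = True
    boundary: bool = False

    @property
    def n_params(self) -> int:
        # fixed effects + 2 RE variances + 1 covariance + gamma shape
        return len(self.beta) + 3 + 1

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    @property
    def coef(self) -> pd.Series:
        return pd.Series(self.beta, index=self.col_names)

    def to_dict(self) -> dict:
        return {
            "spec": {
                "seasons": list(self.spec.seasons),
                "climate_vars": list(self.spec.climate_vars),
                "basis_df": self.spec.basis_df,
                "interaction_mode": self.spec.interaction_mode,
                "interaction_blocks": list(self.spec.interaction_blocks),
                "pp_offset": self.spec.pp_offset,
                "include_ba_fixed": self.spec.include_ba_fixed,
            },
            "col_names": list(self.col_names),
            "col_groups": [sorted(g) for g in self.col_groups],
            "coefficients": {n: float(v) for n, v in zip(self.col_names, self.beta)},
            "se": {n: float(v) for n, v in zip(self.col_names, self.se)},
            "re_cov": self.re_cov.tolist(),
            "gamma_shape": float(self.gamma_shape),
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "n_params": int(self.n_params),
            "n_obs": int(self.n_obs),
            "n_groups": int(self.n_groups),
            "converged": bool(self.converged),
            "boundary": bool(self.boundary),
            "scaler": {
                "var_stats": {k: list(v) for k, v in self.scaler.var_stats.items()},
                "col_stats": {k: list(v) for k, v in self.scaler.col_stats.items()},
            },
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "FittedGrowthModel":
        """Rebuild a fitted model from :meth:`to_dict` output.

        BLUPs are not serialized; reloaded models support population-level
        prediction only.
        """
        spec = ModelSpec(
            seasons=tuple(d["spec"]["seasons"]),
            climate_vars=tuple(d["spec"]["climate_vars"]),
            basis_df=d["spec"]["basis_df"],
            interaction_mode=d["spec"]["interaction_mode"],
            interaction_blocks=tuple(d["spec"]["interaction_blocks"]),
            pp_offset=d["spec"]["pp_offset"],
            include_ba_fixed=d["spec"]["include_ba_fixed"],
        )
        scaler = Scaler(
            var_stats={k: tuple(v) for k, v in d["scaler"]["var_stats"].items()},
            col_stats={k: tuple(v) for k, v in d["scaler"]["col_stats"].items()},
        )
        names = list(d["col_names"])
        return cls(
            spec=spec,
            scaler=scaler,
            col_names=names,
            col_groups=[frozenset(g) for g in d["col_groups"]],
            beta=np.array([d["coefficients"][n] for n in names]),
            se=np.array([d["se"][n] for n in names]),
            re_cov=np.array(d["re_cov"]),
            gamma_shape=d["gamma_shape"],
            loglik=d["loglik"],
            n_obs=d["n_obs"],
            n_groups=d["n_groups"],
            blups=None,
            converged=d["converged"],
            boundary=d["boundary"],
        )

    @classmethod
    def load(cls, path) -> "FittedGrowthModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _init_params(gd: _GroupedData):
    """Gamma GLM (no RE) starting values: IRLS for beta, moments for shape."""
    beta, *_ = np.linalg.lstsq(gd.X, np.log(gd.y), rcond=None)
    for _ in range(4):
        eta = np.clip(gd.X @ beta, -ETA_CLIP, ETA_CLIP)
        zeta = eta + (gd.y - np.exp(eta)) * np.exp(-eta)
        beta, *_ = np.linalg.lstsq(gd.X, zeta, rcond=None)
    eta = np.clip(gd.X @ beta, -ETA_CLIP, ETA_CLIP)
    resid = (gd.y - np.exp(eta)) * np.exp(-eta)
    disp = max(float(np.var(resid)), 1e-4)
    return beta, 1.0 / disp


_THETA_LO = np.array([math.log(1e-4), math.log(1e-4), -10.0, math.log(1e-3)])
_THETA_HI = np.array([math.log(10.0), math.log(10.0), 10.0, math.log(1e8)])


def fit_glmm(
    design: DesignMatrix,
    max_outer: int = 400,
    outer_tol: float = 1e-2,
    verbose: bool = False,
) -> FittedGrowthModel:
    """Fit the gamma log-link GLMM by Laplace-approximated maximum likelihood.

    Outer optimization (Nelder-Mead) runs over the log-Cholesky factor of the
    2x2 random-effect covariance and the log gamma shape; each evaluation
    profiles (beta, b) at their penalized conditional mode.
    """
    if design.y is None:
        raise ValueError("design has no response")
    if design.n_groups < 2:
        raise ValueError("need at least 2 trees to estimate random effects")
    n, p = design.X.shape
    if n < 10 * p:
        import warnings

        warnings.warn(
            f"only {n} observations for {p} fixed parameters (< 10 per parameter)",
            stacklevel=2,
        )
    gd = _GroupedData(design)
    beta0, alpha0 = _init_params(gd)
    state = {"beta": beta0.copy(), "b": np.zeros((gd.G, 2))}

    def objective(t: np.ndarray) -> float:
        t = np.clip(t, _THETA_LO, _THETA_HI)
        L = _chol_from_theta(t[:3])
        alpha = math.exp(t[3])
        Sigma = L @ L.T
        Sinv = linalg.inv(Sigma)
        logdet = 2.0 * math.log(L[0, 0] * L[1, 1])
        beta, b, _ = _pirls(gd, Sinv, alpha, state["beta"], state["b"])
        state["beta"], state["b"] = beta, b
        A = _curvature_obs(gd, Sinv, alpha, beta, b)
        return -_laplace_loglik(gd, beta, b, A, Sinv, alpha, logdet)

    t0 = np.array([math.log(0.2), math.log(0.1), 0.0, math.log(max(alpha0, 0.05))])
    res = optimize.minimize(
        objective,
        t0,
        method="Nelder-Mead",
        options={"xatol": 2e-3, "fatol": outer_tol, "maxfev": max_outer, "adaptive": True},
    )
    t = np.clip(res.x, _THETA_LO, _THETA_HI)
    L = _chol_from_theta(t[:3])
    alpha = math.exp(t[3])
    Sigma = L @ L.T
    Sinv = linalg.inv(Sigma)
    logdet = 2.0 * math.log(L[0, 0] * L[1, 1])
    beta, b, inner_conv = _pirls(
        gd, Sinv, alpha, state["beta"], state["b"], tol=1e-11, max_iter=300
    )
    A = _curvature_obs(gd, Sinv, alpha, beta, b)
    loglik = _laplace_loglik(gd, beta, b, A, Sinv, alpha, logdet)
    # conditional fixed-effect covariance from the observed-information Schur
    # complement at the mode
    eta = np.clip(gd.X @ beta + b[gd.g, 0] + b[gd.g, 1] * gd.zba, -ETA_CLIP, ETA_CLIP)
    w = alpha * gd.y * np.exp(-eta)
    Xw = gd.X * w[:, None]
    Bw = np.stack([gd.gsum_rows(Xw), gd.gsum_rows(gd.X * (w * gd.zba)[:, None])], axis=2)
    S_obs = Xw.T @ gd.X - np.einsum("gpa,gab,gqb->pq", Bw, _inv2x2(A), Bw)
    cov_beta, _ = _solve_spd(S_obs, np.eye(p))
    se = np.sqrt(np.clip(np.diag(cov_beta), 0.0, None))
    sds = np.sqrt(np.diag(Sigma))
    boundary = bool(np.min(sds) < 2e-4)
    blups = pd.DataFrame(
        {"tree_code": design.group_labels, "b_intercept": b[:, 0], "b_ba_slope": b[:, 1]}
    )
    if verbose:
        print(f"outer evals={res.nfev} loglik={loglik:.3f} shape={alpha:.3f} re_sd={sds}")
    return FittedGrowthModel(
        spec=design.spec,
        scaler=design.scaler,
        col_names=list(design.col_names),
        col_groups=list(design.col_groups),
        beta=beta,
        se=se,
        re_cov=Sigma,
        gamma_shape=alpha,
        loglik=loglik,
        n_obs=n,
        n_groups=gd.G,
        blups=blups,
        converged=bool(res.success or res.status == 1) and inner_conv,
        boundary=boundary,
    )


def _group_modes(gd: _GroupedData, beta, Sinv, alpha):
    """Per-group conditional modes of b (beta held fixed) and observed 2x2
    Hessians at those modes."""
    eta_fix = gd.X @ beta
    ends = np.append(gd.starts[1:], gd.y.size)
    modes = np.zeros((gd.G, 2))
    hess = np.zeros((gd.G, 2, 2))
    for j in range(gd.G):
        sl = slice(gd.starts[j], ends[j])
        yj, ej, zj = gd.y[sl], eta_fix[sl], gd.zba[sl]
        b = np.zeros(2)
        for _ in range(80):
            eta = np.clip(ej + b[0] + b[1] * zj, -ETA_CLIP, ETA_CLIP)
            mu = np.exp(eta)
            r = alpha * (yj - mu) / mu
            g = np.array([r.sum(), (r * zj).sum()]) - Sinv @ b
            w = alpha * yj / mu
            H = np.array(
                [[w.sum(), (w * zj).sum()], [(w * zj).sum(), (w * zj**2).sum()]]
            ) + Sinv
            step = np.linalg.solve(H, g)
            if not np.all(np.isfinite(step)):
                break
            if np.abs(step).max() > 5.0:
                step *= 5.0 / np.abs(step).max()
            b = b + step
            if np.abs(step).max() < 1e-12:
                break
        modes[j] = b
        hess[j] = H
    return modes, hess


def marginal_loglik_laplace(
    design: DesignMatrix,
    beta: np.ndarray,
    re_cov: np.ndarray,
    gamma_shape: float,
) -> float:
    """Laplace-approximated marginal log-likelihood at fixed parameters
    (fixed effects, RE covariance, gamma shape)."""
    gd = _GroupedData(design)
    Sigma = np.asarray(re_cov, dtype=float)
    Sinv = linalg.inv(Sigma)
    logdet = float(np.linalg.slogdet(Sigma)[1])
    b, A = _group_modes(gd, np.asarray(beta, dtype=float), Sinv, float(gamma_shape))
    return _laplace_loglik(gd, np.asarray(beta, dtype=float), b, A, Sinv, float(gamma_shape), logdet)


def marginal_loglik_agq(
    design: DesignMatrix,
    beta: np.ndarray,
    re_cov: np.ndarray,
    gamma_shape: float,
    nodes: int = 21,
) -> float:
    """Marginal log-likelihood by adaptive (mode-centered) Gauss-Hermite
    quadrature over the 2-d random effect — the numerically integrated
    reference the Laplace approximation is checked against."""
    gd = _GroupedData(design)
    alpha = float(gamma_shape)
    Sigma = np.asarray(re_cov, dtype=float)
    Sinv = linalg.inv(Sigma)
    logdet_sigma = float(np.linalg.slogdet(Sigma)[1])
    x, wq = np.polynomial.hermite.hermgauss(nodes)
    XX, YY = np.meshgrid(x, x, indexing="ij")
    nodes2 = np.column_stack([XX.ravel(), YY.ravel()])
    logw2 = (np.log(wq)[:, None] + np.log(wq)[None, :]).ravel() + (XX**2 + YY**2).ravel()
    const = float(
        gd.y.size * (alpha * math.log(alpha) - special.gammaln(alpha))
        + (alpha - 1.0) * gd.logy_sum
    )
    total = const
    beta = np.asarray(beta, dtype=float)
    eta_fix = gd.X @ beta
    ends = np.append(gd.starts[1:], gd.y.size)
    modes, hess = _group_modes(gd, beta, Sinv, alpha)
    for j in range(gd.G):
        sl = slice(gd.starts[j], ends[j])
        yj, ej, zj = gd.y[sl], eta_fix[sl], gd.zba[sl]

        def f(b0, b1):
            eta = np.clip(ej + b0 + b1 * zj, -ETA_CLIP, ETA_CLIP)
            cond = -alpha * (eta + yj * np.exp(-eta)).sum()
            quad = -0.5 * (
                Sinv[0, 0] * b0**2 + 2 * Sinv[0, 1] * b0 * b1 + Sinv[1, 1] * b1**2
            )
            return cond + quad - math.log(2 * math.pi) - 0.5 * logdet_sigma

        LH = np.linalg.cholesky(hess[j])
        shift = math.sqrt(2.0) * linalg.solve_triangular(LH, nodes2.T, lower=True, trans="T").T
        bs = modes[j][None, :] + shift
        fv = np.array([f(bb[0], bb[1]) for bb in bs])
        logint = (
            math.log(2.0)  # 2^{d/2} with d = 2
            - float(np.log(np.diag(LH)).sum())
            + special.logsumexp(logw2 + fv)
        )
        total += logint
    return float(total)


# ---------------------------------------------------------------------------
# Nested-model comparison ladder
# ---------------------------------------------------------------------------

def default_ladder() -> list[tuple[str, tuple[str, ...]]]:
    """The 8-row validation ladder: null, single groups, pairs, full model."""
    return [
        ("Null model", ()),
        ("AI", ("ai",)),
        ("Geo", ("geo",)),
        ("AI+Geo", ("ai", "geo")),
        ("Cli", ("cli",)),
        ("AI+Cli", ("ai", "cli")),
        ("Cli+Geo", ("cli", "geo")),
        ("Full model", ("ai", "cli", "geo")),
    ]


def compare_models(
    design: DesignMatrix,
    ladder: list[tuple[str, tuple[str, ...]]] | None = None,
    max_outer: int = 300,
    return_models: bool = False,
):
    """Fit every group-inclusion pattern on identical data and tabulate
    AIC, delta-AIC and likelihood-ratio chi-square tests.

    Each model's chi-square compares it against the largest strictly nested
    model in the ladder (the null model at minimum); df is the difference in
    parameter counts.
    """
    ladder = ladder if ladder is not None else default_ladder()
    fits: list[FittedGrowthModel] = []
    rows = []
    for label, pattern in ladder:
        sub = design.subset_groups(tuple(pattern))
        fit = fit_glmm(sub, max_outer=max_outer)
        fits.append(fit)
        rows.append({"label": label, "pattern": tuple(pattern)})
    aics = np.array([f.aic for f in fits])
    best = aics.min()
    out = []
    for i, (row, fit) in enumerate(zip(rows, fits)):
        pat = set(row["pattern"])
        nested = [
            j
            for j in range(i)
            if set(ladder[j][1]) <= pat
        ]
        if nested:
            j = max(nested, key=lambda k: fits[k].n_params)
            chisq = max(2.0 * (fit.loglik - fits[j].loglik), 0.0)
            df = fit.n_params - fits[j].n_params
            pval = float(stats.chi2.sf(chisq, df)) if df > 0 else math.nan
            ref = ladder[j][0]
        else:
            chisq, df, pval, ref = math.nan, 0, math.nan, ""
        out.append(
            {
                "label": row["label"],
                "ai": "ai" in pat,
                "cli": "cli" in pat,
                "geo": "geo" in pat,
                "n_params": fit.n_params,
                "loglik": fit.loglik,
                "aic": fit.aic,
                "delta_aic": fit.aic - best,
                "chisq": chisq,
                "df": df,
                "p": pval,
                "vs": ref,
            }
        )
    table = pd.DataFrame(out)
    return (table, fits) if return_models else table


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict_bai(
    model: FittedGrowthModel,
    newdata: pd.DataFrame,
    ba_fixed: float | None = None,
    population_level: bool = True,
) -> np.ndarray:
    """Predicted BAI (mm^2/yr) for raw covariate rows.

    ``ba_fixed`` overrides per-row ``ba_prev`` with a constant reference basal
    area (mm^2). Population-level predictions set the random effects to zero;
    otherwise rows must carry ``tree_code`` matching the training trees and
    their BLUPs are added.
    """
    frame = newdata.copy()
    if ba_fixed is not None:
        frame["ba_prev"] = float(ba_fixed)
    if "ba_prev" not in frame.columns:
        raise ValueError("newdata needs ba_prev or an explicit ba_fixed")
    dm = design_from_frame(frame, model.spec, model.scaler, with_response=False)
    full_names = dm.col_names
    if full_names != model.col_names:
        # model may be a reduced (ladder) fit: align by column name
        name_to_i = {n: i for i, n in enumerate(full_names)}
        missing = [n for n in model.col_names if n not in name_to_i]
        if missing:
            raise ValueError(f"newdata design lacks model columns {missing[:5]}")
        Xm = dm.X[:, [name_to_i[n] for n in model.col_names]]
    else:
        Xm = dm.X
    eta = Xm @ model.beta
    if not population_level:
        if "tree_code" not in frame.columns:
            raise ValueError("tree-level prediction needs a tree_code column")
        bl = model.blups.set_index("tree_code")
        codes = frame["tree_code"]
        unknown = set(codes) - set(bl.index)
        if unknown:
            raise ValueError(f"unknown trees: {sorted(unknown)[:5]}")
        eta = eta + bl.loc[codes, "b_intercept"].to_numpy() + bl.loc[
            codes, "b_ba_slope"
        ].to_numpy() * dm.z_ba
    return np.exp(np.clip(eta, -ETA_CLIP, ETA_CLIP))
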