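"""Environmental heterogeneity as multivariate dispersion.

The heterogeneity of the environment available to a colony in a given year is
scored as the mean distance of grid-cell observations from their colony-year
group centre (centroid or spatial median) in the principal-coordinate
ordination of a Euclidean distance matrix of the six standardized environmental
variables — the multivariate-dispersion construction of PERMDISP.  Because the
input distances are Euclidean, the ordination is an isometry: dispersion
computed on all PCoA axes equals dispersion computed directly in the
standardized variable space, which this module exploits (and its tests assert
to 1e-9) when sample sizes make the n x n eigendecomposition wasteful.

Group differences in dispersion are tested with the PERMDISP permutation F
test; colony and year effects on the resulting heterogeneity values with a
two-way ANOVA plus Tukey HSD; and the sensitivity of heterogeneity to the
foraging radius used to extract the environment with a linear regression.

Standardization is pooled across all colony-years (one shared distance space,
sample-SD convention), so heterogeneity values are comparable between groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geo
from .errors import (
    DegenerateColumnError,
    DegenerateGroupError,
    EmptyDomainError,
    InvalidDistanceError,
)
from .rasters import LAYER_NAMES, EnvRasterStack

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# sampling and standardization
# ---------------------------------------------------------------------------

def extract_env_samples(stack: EnvRasterStack, colony_latlon, radius_km: float) -> pd.DataFrame:
    """One row per grid cell whose centre lies within the foraging radius.

    Cells with any missing layer are dropped; the count of dropped cells is
    recorded in ``DataFrame.attrs['n_dropped']``.
    """
    if radius_km <= 0:
        raise ValueError("radius must be positive")
    lat2d, lon2d = stack.cell_centers()
    dist = geo.haversine_km(lat2d, lon2d, colony_latlon[0], colony_latlon[1])
    inside = dist <= radius_km
    if not np.any(inside):
        raise EmptyDomainError(f"no grid cells within {radius_km} km of the colony")
    data = {name: stack.layers[name][inside] for name in stack.layers}
    table = pd.DataFrame(data)
    complete = table.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropped %d cells with missing layers", n_dropped)
    out = table.loc[complete].reset_index(drop=True)
    out.attrs["n_dropped"] = n_dropped
    return out


def standardize_env(table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Standardize environmental columns to mean 0, SD 1 pooled over all rows.

    Uses the sample-SD convention (denominator n-1, as R's ``scale``), so a
    single-group column {1, 2, 3} maps to {-1, 0, 1}.  Non-environmental
    columns (group labels etc.) pass through unchanged.
    """
    columns = [c for c in (columns or LAYER_NAMES) if c in table.columns]
    out = table.copy()
    for col in columns:
        x = out[col].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise DegenerateColumnError(f"environmental column {col!r} has zero variance")
        out[col] = (x - x.mean()) / sd
    return out


# ---------------------------------------------------------------------------
# principal coordinate analysis
# ---------------------------------------------------------------------------

@dataclass
class Ordination:
    """PCoA embedding: coordinates, eigenvalues and variance explained."""

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    variance_explained: np.ndarray


def pcoa(distances, negative_tol_factor: float = 1e-8) -> Ordination:
    """Principal coordinate analysis of a symmetric distance matrix.

    Applies Gower double-centring to ``-D**2 / 2``, eigendecomposes, and keeps
    axes with positive eigenvalues; coordinates are eigenvectors scaled by the
    square root of their eigenvalue.  With a Euclidean input matrix the
    spectrum is non-negative up to round-off; eigenvalues below
    ``-negative_tol_factor * max_eigenvalue`` raise, tiny negatives are
    dropped.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise InvalidDistanceError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise InvalidDistanceError("distance matrix must be symmetric")
    if np.any(np.abs(np.diag(d)) > 1e-12) or np.any(d < -1e-12):
        raise InvalidDistanceError("distances must be non-negative with a zero diagonal")
    n = d.shape[0]
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    b = a - row - col + a.mean()
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if eigval.size and eigval[0] > 0 and np.any(eigval < -negative_tol_factor * eigval[0]):
        raise InvalidDistanceError(
            "distance matrix is strongly non-Euclidean (large negative eigenvalues)")
    keep = eigval > max(eigval[0], 0) * 1e-12 if eigval.size else np.zeros(0, bool)
    eigval = eigval[keep]
    coords = eigvec[:, keep] * np.sqrt(eigval)
    total = eigval.sum()
    varexp = eigval / total if total > 0 else np.zeros_like(eigval)
    return Ordination(coordinates=coords, eigenvalues=eigval, variance_explained=varexp)


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def _spatial_median(x: np.ndarray, tol: float = 1e-10, maxiter: int = 500) -> np.ndarray:
    """Geometric (spatial) median by Weiszfeld iteration with the standard
    modification for iterates that land on a data point."""
    y = x.mean(axis=0)
    for _ in range(maxiter):
        d = np.linalg.norm(x - y, axis=1)
        on_point = d < 1e-12
        if np.any(on_point):
            # Vardi-Zhang step: treat the coincident point's pull separately
            d = np.where(on_point, np.inf, d)
        w = 1.0 / d
        wsum = w.sum()
        if wsum == 0:
            return y
        t = (w[:, None] * x).sum(axis=0) / wsum
        if np.any(on_point):
            r = np.linalg.norm(((x - y) * w[:, None]).sum(axis=0))
            k = on_point.sum()
            if r <= k:
                return y
            t = max(0.0, 1.0 - k / r) * t + min(1.0, k / r) * y
        if np.linalg.norm(t - y) <= tol * max(1.0, np.linalg.norm(y)):
            return t
        y = t
    return y


@dataclass
class DispersionResult:
    """Per-observation distances to group centres and the per-group mean (H)."""

    distances: np.ndarray
    H: pd.Series
    centers: dict
    center_type: str


def dispersion(coords, groups, center: str = "median") -> DispersionResult:
    """Distance of each observation to its own group's centre; H = group mean.

    ``coords`` may be PCoA coordinates or (equivalently, for the Euclidean
    metric used throughout) the standardized variable matrix itself.  ``center``
    is ``'median'`` (spatial median, the PERMDISP default) or ``'centroid'``.
    """
    if center not in ("median", "centroid"):
        raise ValueError(f"unknown center type {center!r}")
    x = np.asarray(coords, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    groups = np.asarray(groups)
    dist = np.empty(len(x))
    centers = {}
    h = {}
    for g in pd.unique(groups):
        mask = groups == g
        xg = x[mask]
        if len(xg) == 0:
            raise DegenerateGroupError(f"group {g!r} has no observations")
        c = xg.mean(axis=0) if center == "centroid" else _spatial_median(xg)
        centers[g] = c
        dg = np.linalg.norm(xg - c, axis=1)
        dist[mask] = dg
        h[g] = float(dg.mean())
    return DispersionResult(distances=dist, H=pd.Series(h, name="H"),
                            centers=centers, center_type=center)


def _anova_f(values: np.ndarray, groups: np.ndarray) -> float:
    """One-way ANOVA F statistic (between/within mean squares)."""
    grand = values.mean()
    ss_b = ss_w = 0.0
    k = 0
    for g in pd.unique(groups):
        v = values[groups == g]
        k += 1
        ss_b += len(v) * (v.mean() - grand) ** 2
        ss_w += ((v - v.mean()) ** 2).sum()
    df_b = k - 1
    df_w = len(values) - k
    if df_b <= 0 or df_w <= 0:
        raise DegenerateGroupError("need at least 2 groups with replication")
    if ss_w == 0:
        return np.inf if ss_b > 0 else 0.0
    return (ss_b / df_b) / (ss_w / df_w)


@dataclass
class PermdispResult:
    F: float
    p: float
    n_perm: int
    center_type: str


def permdisp_test(coords, groups, n_perm: int = 999, seed: int = 0,
                  center: str = "median") -> PermdispResult:
    """PERMDISP: permutation F test for homogeneity of multivariate dispersion.

    The observed F compares per-observation distances to group centres across
    groups; under each of ``n_perm`` free permutations of the group labels the
    centres and distances are recomputed and F recalculated.  The p-value uses
    the add-one convention ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)`` and is
    deterministic given ``seed``.
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    x = np.asarray(coords, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    groups = np.asarray(groups)
    uniq, counts = np.unique(groups, return_counts=True)
    if uniq.size < 2:
        raise DegenerateGroupError("PERMDISP needs at least two groups")
    if np.any(counts < 2):
        small = uniq[counts < 2]
        raise DegenerateGroupError(f"groups {small} have fewer than 2 observations")
    obs = dispersion(x, groups, center=center)
    f_obs = _anova_f(obs.distances, groups)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        d = dispersion(x, perm, center=center)
        if _anova_f(d.distances, perm) >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermdispResult(F=float(f_obs), p=float(p), n_perm=n_perm, center_type=center)


# ---------------------------------------------------------------------------
# colony-year heterogeneity table and follow-up tests
# ---------------------------------------------------------------------------

def heterogeneity_table(samples: pd.DataFrame, center: str = "median",
                        use_pcoa: bool = False, group_cols=("colony_id", "year")) -> pd.DataFrame:
    """Heterogeneity H per colony-year from pooled environmental samples.

    ``samples`` holds one row per grid cell with the six layer columns plus
    group labels.  Layers are standardized pooled over all rows, then H is the
    mean distance to the group centre — computed in the standardized space
    directly, or in the full PCoA ordination when ``use_pcoa=True`` (identical
    for this Euclidean metric; the flag exists for explicit verification).
    """
    layer_cols = [c for c in LAYER_NAMES if c in samples.columns]
    std = standardize_env(samples, columns=layer_cols)
    x = std[layer_cols].to_numpy(dtype=float)
    if use_pcoa:
        from scipy.spatial.distance import squareform, pdist

        ordination = pcoa(squareform(pdist(x)))
        x = ordination.coordinates
    key = std[list(group_cols)].astype(str).agg("|".join, axis=1).to_numpy()
    disp = dispersion(x, key, center=center)
    rows = []
    for label, h in disp.H.items():
        parts = label.split("|")
        row = dict(zip(group_cols, parts))
        row["H"] = h
        row["n_cells"] = int((key == label).sum())
        rows.append(row)
    out = pd.DataFrame(rows)
    if "year" in out.columns:
        out["year"] = out["year"].astype(int)
    return out


@dataclass
class AnovaTukeyResult:
    anova: pd.DataFrame
    tukey: dict


def het_anova_tukey(h_table: pd.DataFrame, response: str = "H") -> AnovaTukeyResult:
    """Two-way ANOVA (colony, year as factors) on H plus Tukey HSD post hoc tests.

    A factor with a single level is skipped with a warning.  Degenerate
    zero-variance effects are reported as F = 0, p = 1.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = h_table.copy()
    df["colony_id"] = df["colony_id"].astype(str)
    df["year"] = df["year"].astype(str)
    factors = []
    for fac in ("colony_id", "year"):
        if df[fac].nunique() >= 2:
            factors.append(fac)
        else:
            logger.warning("factor %s has a single level; skipped from the ANOVA", fac)
    if not factors:
        raise DegenerateGroupError("no factor with at least two levels")
    formula = f"{response} ~ " + " + ".join(f"C({f})" for f in factors)
    model = ols(formula, data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    # zero-variance responses: 0/0 -> define F = 0, p = 1
    for idx in anova.index:
        if idx == "Residual":
            continue
        if anova.loc[idx, "sum_sq"] < 1e-12:
            anova.loc[idx, "F"] = 0.0
            anova.loc[idx, "PR(>F)"] = 1.0
        elif not np.isfinite(anova.loc[idx, "F"]):
            anova.loc[idx, "F"] = np.inf
            anova.loc[idx, "PR(>F)"] = 0.0
    tukey = {}
    for fac in factors:
        try:
            tk = pairwise_tukeyhsd(df[response].to_numpy(), df[fac].to_numpy())
            tukey[fac] = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
        except Exception as exc:  # degenerate spread: report and continue
            logger.warning("Tukey HSD failed for %s: %s", fac, exc)
    return AnovaTukeyResult(anova=anova, tukey=tukey)


@dataclass
class RadiusSensitivity:
    slope: float
    F: float
    p: float
    r2: float


def radius_sensitivity(h: np.ndarray, radius: np.ndarray) -> RadiusSensitivity:
    """Linear regression of heterogeneity on the foraging radius used to extract it."""
    import statsmodels.api as sm

    h = np.asarray(h, dtype=float)
    radius = np.asarray(radius, dtype=float)
    if h.size < 3:
        raise ValueError("need at least 3 colonies")
    x = sm.add_constant(radius)
    fit = sm.OLS(h, x).fit()
    if fit.ssr < 1e-14 and fit.ess < 1e-14:
        return RadiusSensitivity(slope=0.0, F=0.0, p=1.0, r2=0.0)
    f = float(fit.fvalue) if np.isfinite(fit.fvalue) else np.inf
    p = float(fit.f_pvalue) if np.isfinite(fit.f_pvalue) else 0.0
    return RadiusSensitivity(slope=float(fit.params[1]), F=f, p=p, r2=float(fit.rsquared))
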