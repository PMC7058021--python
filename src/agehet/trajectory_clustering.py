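"""Cluster genes by the shape of their heterogeneity-vs-age trajectory.

Sample sizes differ between datasets, so running k-means on raw per-sample
heterogeneity levels would weight datasets unequally.  Instead, per gene and
dataset the |residual| series is scaled (mean 0, sd 1), smoothed by a cubic
smoothing spline with 3 effective degrees of freedom, and evaluated at 11
equally spaced points over the dataset's transformed age range.  The
concatenated interpolated values (11 columns per dataset) form the feature
matrix for k-means.

The smoothing spline is the classical penalized fit

    min_f  sum_i w_i (y_i - f(x_i))^2 + lam * int f''(t)^2 dt

solved in its Reinsch form ``f = (W + lam K)^-1 W y`` on the unique sorted
abscissae; the penalty ``lam`` is chosen by bisection so that the trace of the
smoother matrix (the effective degrees of freedom) hits the target.  The
penalty annihilates linear functions, so a linear trend is reproduced exactly
for any lam.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from sklearn.cluster import KMeans

from .core_data import ExpressionDataset

__all__ = ["smoothing_spline_fit", "smooth_and_interpolate", "cluster_trajectories"]


def _second_difference_penalty(x: np.ndarray) -> np.ndarray:
    """Reinsch penalty K = D' W^-1 D for a natural cubic smoothing spline.

    ``x`` must be strictly increasing with at least 3 points.  D is the
    second-difference operator scaled by the knot spacings and W the
    tridiagonal Gram matrix of the natural-spline second-derivative basis
    (Green & Silverman parameterization).
    """
    n = x.size
    h = np.diff(x)
    D = np.zeros((n - 2, n))
    for i in range(n - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
    W = np.zeros((n - 2, n - 2))
    for i in range(n - 2):
        W[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < n - 2:
            W[i, i + 1] = W[i + 1, i] = h[i + 1] / 6.0
    return D.T @ np.linalg.solve(W, D)


def smoothing_spline_fit(
    x, y, df: float = 3.0, grid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Cubic smoothing spline with a target effective degrees of freedom.

    Duplicate abscissae are collapsed to their mean response with weight equal
    to their multiplicity.  Returns ``(fitted_at_unique_x, values_at_grid)``;
    grid evaluation interpolates the fitted values with a natural cubic
    spline.  ``df`` must lie in (2, n_unique]; df -> 2 is the least-squares
    line, df = n_unique the interpolating spline.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    ux, inv, counts = np.unique(x, return_inverse=True, return_counts=True)
    n = ux.size
    if n < 3:
        raise ValueError("need at least 3 distinct abscissae for a smoothing spline")
    if not 2 < df <= n:
        raise ValueError(f"df must be in (2, {n}], got {df}")
    uy = np.bincount(inv, weights=y) / counts
    w = counts.astype(float)
    K = _second_difference_penalty(ux)
    W = np.diag(w)

    def smoother_df(lam: float) -> float:
        S = np.linalg.solve(W + lam * K, W)
        return float(np.trace(S))

    # bracket lam: df is decreasing in lam, from n (lam -> 0) to 2 (lam -> inf)
    lo, hi = 1e-12, 1.0
    while smoother_df(hi) > df:
        hi *= 10.0
        if hi > 1e14:
            break
    while smoother_df(lo) < df:
        lo /= 10.0
        if lo < 1e-300:
            break
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if smoother_df(mid) > df:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1 + 1e-10:
            break
    lam = np.sqrt(lo * hi)
    fitted = np.linalg.solve(W + lam * K, w * uy)
    if grid is None:
        return fitted, fitted
    spline = CubicSpline(ux, fitted, bc_type="natural")
    return fitted, spline(np.asarray(grid, float))


def smooth_and_interpolate(
    datasets: Mapping[str, ExpressionDataset],
    heterogeneity: Mapping[str, pd.DataFrame],
    gene_set: Sequence[str],
    df: float = 3.0,
    n_points: int = 11,
    age_scale: str = "fourth_root",
) -> pd.DataFrame:
    """Build the trajectory feature matrix: genes x (dataset x age-grid).

    ``heterogeneity[name]`` holds per-gene |residual| levels (genes x
    samples).  Per gene and dataset the levels are scaled to mean 0 / sd 1,
    spline-smoothed at ``df`` effective degrees of freedom, and evaluated at
    ``n_points`` equally spaced transformed ages spanning that dataset's age
    range.  Genes with constant heterogeneity in any dataset are dropped with
    a warning.  A dataset with fewer samples than ``n_points`` is an error.
    """
    if len(gene_set) == 0:
        raise ValueError("gene_set is empty")
    gene_set = list(gene_set)
    blocks: dict[str, pd.DataFrame] = {}
    dropped: set[str] = set()
    for name, ds in datasets.items():
        if ds.n_samples < n_points:
            raise ValueError(
                f"dataset {name!r} has {ds.n_samples} samples, fewer than the "
                f"{n_points} interpolation points"
            )
        H = heterogeneity[name].loc[gene_set].to_numpy(float)
        t = ds.ages_transformed(age_scale)
        grid = np.linspace(t.min(), t.max(), n_points)
        sd = H.std(axis=1, ddof=1)
        flat = sd == 0
        for g in np.asarray(gene_set)[flat]:
            dropped.add(str(g))
        Hs = (H - H.mean(axis=1, keepdims=True)) / np.where(flat, 1.0, sd)[:, None]
        values = np.full((len(gene_set), n_points), np.nan)
        for i in range(len(gene_set)):
            if flat[i]:
                continue
            _, values[i] = smoothing_spline_fit(t, Hs[i], df=df, grid=grid)
        blocks[name] = pd.DataFrame(
            values,
            index=pd.Index(gene_set, name="gene_id"),
            columns=[f"{name}:t{j}" for j in range(n_points)],
        )
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} gene(s) with constant heterogeneity: {sorted(dropped)}",
            stacklevel=2,
        )
    matrix = pd.concat(blocks.values(), axis=1)
    keep = [g for g in gene_set if g not in dropped]
    return matrix.loc[keep]


def cluster_trajectories(
    matrix: pd.DataFrame, k: int = 8, seed: int = 0, n_init: int = 10
) -> tuple[pd.Series, float, pd.DataFrame]:
    """k-means over trajectory rows.

    Returns (assignments, within-cluster sum of squares, cluster-mean
    trajectories).  Multiple restarts (``n_init``) keep the best inertia;
    deterministic given ``seed``.
    """
    if matrix.isna().any().any():
        raise ValueError("trajectory matrix contains missing values")
    if k > matrix.shape[0]:
        raise ValueError(f"k = {k} exceeds the number of genes ({matrix.shape[0]})")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(matrix.to_numpy(float))
    assignments = pd.Series(labels, index=matrix.index, name="cluster")
    centers = pd.DataFrame(km.cluster_centers_, columns=matrix.columns)
    centers.index.name = "cluster"
    return assignments, float(km.inertia_), centers
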