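"""Spatial analysis of interneuron positions in the spinal hemisection.

Coordinates are measured in the transverse plane relative to the midpoint
of the central canal at (0, 0), +x lateral and -y ventral, and are
standardized so the central-canal-to-lateral distance is 650 um and the
central-canal-to-ventral distance is 400 um.  Distributions are compared
with the two-dimensional Kolmogorov-Smirnov test in the Fasano-Franceschini
quadrant form, with a label-permutation p value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

__all__ = ["LATERAL_UM", "VENTRAL_UM", "normalize_position", "density_grid",
           "ks2d", "ks2d_statistic", "KS2DResult"]

LATERAL_UM = 650.0
VENTRAL_UM = 400.0


def normalize_position(points: pd.DataFrame, extents: pd.DataFrame,
                       section_key: str = "section") -> pd.DataFrame:
    """Standardize raw (x, y) positions section by section.

    ``points`` needs columns x_um, y_um and a section id; ``extents`` is
    indexed by section with columns ``lateral`` (central canal to lateral
    boundary, um) and ``ventral`` (central canal to ventral boundary, um).
    x' = x * 650 / L and y' = y * 400 / V; the single ventral factor also
    applies to dorsal (positive-y) points.  The origin is fixed.
    """
    out = points.copy()
    L = extents["lateral"].reindex(points[section_key]).to_numpy(dtype=float)
    V = extents["ventral"].reindex(points[section_key]).to_numpy(dtype=float)
    if np.any(~np.isfinite(L)) or np.any(~np.isfinite(V)):
        missing = sorted(set(points[section_key]) - set(extents.index))
        raise ValueError(f"sections without extents: {missing}")
    if np.any(L <= 0) or np.any(V <= 0):
        raise ValueError("section extents must be positive")
    out["x_std"] = points["x_um"].to_numpy(dtype=float) * LATERAL_UM / L
    out["y_std"] = points["y_um"].to_numpy(dtype=float) * VENTRAL_UM / V
    return out


def density_grid(points: np.ndarray, bandwidth=None,
                 grid_size: int = 100, padding: float = 0.1) -> tuple:
    """2-D Gaussian kernel density on a regular grid.

    Returns ``(xx, yy, density)``; Scott's rule bandwidth by default.  The
    grid covers the data range plus ``padding`` (fractional margin), so the
    grid integral of the density is close to 1 for interior distributions.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 2:
        raise ValueError("density estimation needs at least two points")
    jitter = 0.0
    if np.allclose(pts.var(axis=0), 0):
        jitter = 1e-6
        pts = pts + jitter * np.random.default_rng(0).standard_normal(pts.shape)
    kde = gaussian_kde(pts.T, bw_method=bandwidth)
    span = pts.max(axis=0) - pts.min(axis=0)
    lo = pts.min(axis=0) - padding * np.maximum(span, 1.0)
    hi = pts.max(axis=0) + padding * np.maximum(span, 1.0)
    xs = np.linspace(lo[0], hi[0], grid_size)
    ys = np.linspace(lo[1], hi[1], grid_size)
    xx, yy = np.meshgrid(xs, ys)
    dens = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
    return xx, yy, dens


def _max_quadrant_diff(origins: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Max over origins and open quadrants of |F_a - F_b| (strict inequalities)."""
    ox = origins[:, 0][:, None]
    oy = origins[:, 1][:, None]
    a_gx = a[None, :, 0] > ox   # origins x points
    a_gy = a[None, :, 1] > oy
    a_lx = a[None, :, 0] < ox
    a_ly = a[None, :, 1] < oy
    b_gx = b[None, :, 0] > ox
    b_gy = b[None, :, 1] > oy
    b_lx = b[None, :, 0] < ox
    b_ly = b[None, :, 1] < oy
    best = 0.0
    for qa_x, qa_y, qb_x, qb_y in (
        (a_gx, a_gy, b_gx, b_gy),
        (a_lx, a_gy, b_lx, b_gy),
        (a_lx, a_ly, b_lx, b_ly),
        (a_gx, a_ly, b_gx, b_ly),
    ):
        fa = (qa_x & qa_y).mean(axis=1)
        fb = (qb_x & qb_y).mean(axis=1)
        d = np.abs(fa - fb).max()
        if d > best:
            best = float(d)
    return best


def ks2d_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Fasano-Franceschini two-sample statistic.

    With each sample's points as quadrant origins in turn, D is the average
    of the two maxima of the absolute difference in open-quadrant empirical
    fractions.  D = 0 for identical point multisets; D -> 1 for samples
    with disjoint quadrant support.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d1 = _max_quadrant_diff(a, a, b)
    d2 = _max_quadrant_diff(b, a, b)
    return 0.5 * (d1 + d2)


@dataclass
class KS2DResult:
    statistic: float
    pvalue: float
    n_a: int
    n_b: int
    n_perm: int


def ks2d(a, b, n_perm: int = 1000, seed: int = 0) -> KS2DResult:
    """Two-dimensional KS test with a label-permutation p value.

    p = (1 + #{D_perm >= D_obs}) / (n_perm + 1), so p is bounded below by
    1/(n_perm + 1).  Samples below 10 points raise a warning.
    """
    a = np.asarray(a, dtype=float).reshape(-1, 2)
    b = np.asarray(b, dtype=float).reshape(-1, 2)
    if min(len(a), len(b)) < 10:
        warnings.warn("fewer than 10 points in a sample; the permutation "
                      "p value will be coarse")
    d_obs = ks2d_statistic(a, b)
    rng = np.random.default_rng(seed)
    pooled = np.vstack([a, b])
    n_a = len(a)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(pooled))
        pa, pb = pooled[perm[:n_a]], pooled[perm[n_a:]]
        if ks2d_statistic(pa, pb) >= d_obs - 1e-12:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return KS2DResult(statistic=d_obs, pvalue=p, n_a=len(a), n_b=len(b),
                      n_perm=n_perm)
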