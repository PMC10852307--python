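"""Kriged security surfaces, five-level classification, Moran's I.

Unit-level risk values are interpolated to a continuous surface by ordinary
kriging with a spherical semivariogram fitted to the empirical
semivariogram (weighted least squares).  The surface is then cut into five
security levels with fixed thresholds calibrated on the 2010 epoch:

    I   (safe)            ERI < 0.0061
    II  (relatively safe) 0.0061 ≤ ERI < 0.0079
    III (medium)          0.0079 ≤ ERI < 0.0096
    IV  (relatively unsafe) 0.0096 ≤ ERI < 0.012
    V   (unsafe)          ERI ≥ 0.012

The reporting grid defaults to 500 m cells, so every level area is a
multiple of 25 hm².  Spatial autocorrelation of unit values is measured by
global Moran's I under row-standardized queen (default) or rook contiguity
with a seeded permutation test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, spatial

logger = logging.getLogger(__name__)

#: Printed level break values (lower edges of levels II..V).
DEFAULT_ERI_THRESHOLDS = (0.0061, 0.0079, 0.0096, 0.012)
LEVEL_LABELS = ("I", "II", "III", "IV", "V")


# ---------------------------------------------------------------------------
# Ordinary kriging


def _spherical(h: np.ndarray, nugget: float, sill: float, rng: float) -> np.ndarray:
    """Spherical semivariogram; ``sill`` is the partial sill."""
    h = np.asarray(h, dtype=float)
    g = np.where(
        h < rng,
        nugget + sill * (1.5 * h / rng - 0.5 * (h / rng) ** 3),
        nugget + sill,
    )
    return np.where(h == 0, 0.0, g)


def fit_spherical_variogram(
    points: np.ndarray, values: np.ndarray, n_lags: int = 12, nugget: float | None = None
) -> tuple[float, float, float]:
    """Fit (nugget, partial sill, range) to the empirical semivariogram.

    Pair semivariances are binned by distance into ``n_lags`` lags up to
    half the maximum pair distance and fitted by count-weighted least
    squares.  Passing ``nugget`` pins the nugget (0 gives an exact
    interpolator).
    """
    d = spatial.distance.pdist(points)
    sv = spatial.distance.pdist(values[:, None], metric="sqeuclidean") / 2.0
    dmax = d.max()
    if dmax == 0:
        return 0.0, max(values.var(), 1e-12), 1.0
    edges = np.linspace(0, dmax / 2.0, n_lags + 1)
    which = np.digitize(d, edges[1:-1])
    lag_h, lag_g, lag_n = [], [], []
    for b in range(n_lags):
        sel = which == b
        if sel.sum() >= 2:
            lag_h.append(d[sel].mean())
            lag_g.append(sv[sel].mean())
            lag_n.append(sel.sum())
    lag_h, lag_g, lag_n = map(np.asarray, (lag_h, lag_g, lag_n))
    var0 = max(values.var(), 1e-12)
    if len(lag_h) < 3:
        return (nugget or 0.0), var0, dmax / 2.0
    fixed_nugget = nugget

    def model(h, *theta):
        if fixed_nugget is None:
            n0, s, r = theta
        else:
            n0 = fixed_nugget
            s, r = theta
        return _spherical(h, n0, s, r)

    if fixed_nugget is None:
        p0 = [0.0, var0, dmax / 4.0]
        bounds = ([0, 1e-12, edges[1] or 1e-6], [var0 * 2, var0 * 10, dmax * 2])
    else:
        p0 = [var0, dmax / 4.0]
        bounds = ([1e-12, edges[1] or 1e-6], [var0 * 10, dmax * 2])
    try:
        popt, _ = optimize.curve_fit(
            model, lag_h, lag_g, p0=p0, bounds=bounds, sigma=1.0 / np.sqrt(lag_n),
            maxfev=10_000,
        )
    except RuntimeError:
        popt = p0
    if fixed_nugget is None:
        return float(popt[0]), float(popt[1]), float(popt[2])
    return float(fixed_nugget), float(popt[0]), float(popt[1])


def krige(
    points: np.ndarray,
    values: np.ndarray,
    query: np.ndarray,
    nugget: float | None = 0.0,
    variogram: tuple[float, float, float] | None = None,
) -> np.ndarray:
    """Ordinary kriging predictions at ``query`` locations.

    With nugget 0 (default) the interpolator is exact: predictions at the
    sample points reproduce the sample values.  On a singular kriging
    system, falls back to inverse-distance weighting with a logged warning.
    Requires at least 10 points.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    query = np.asarray(query, dtype=float)
    n = len(points)
    if n < 10:
        raise ValueError(f"kriging needs at least 10 points, got {n}")
    if np.ptp(values) == 0:
        return np.full(len(query), values[0])
    if variogram is None:
        variogram = fit_spherical_variogram(points, values, nugget=nugget)
    n0, s, r = variogram
    dmat = spatial.distance.cdist(points, points)
    gamma = _spherical(dmat, n0, s, r)
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = gamma
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    A[n, n] = 0.0
    dq = spatial.distance.cdist(query, points)
    B = np.empty((len(query), n + 1))
    B[:, :n] = _spherical(dq, n0, s, r)
    B[:, n] = 1.0
    try:
        lam = linalg.solve(A, B.T, assume_a="sym")
    except linalg.LinAlgError:
        logger.warning("singular kriging system; falling back to IDW")
        return _idw(points, values, query)
    pred = values @ lam[:n]
    # Exactness at coincident points is enforced explicitly: zero-nugget
    # kriging honors data, but float round-off can leave ~1e-12 residuals.
    if n0 == 0:
        exact = dq.min(axis=1) == 0
        if exact.any():
            pred[exact] = values[dq[exact].argmin(axis=1)]
    return pred


def _idw(points: np.ndarray, values: np.ndarray, query: np.ndarray, power: float = 2.0) -> np.ndarray:
    d = spatial.distance.cdist(query, points)
    with np.errstate(divide="ignore"):
        w = 1.0 / d**power
    out = np.empty(len(query))
    hit = d.min(axis=1) == 0
    out[hit] = values[d[hit].argmin(axis=1)]
    rest = ~hit
    if rest.any():
        wr = w[rest]
        out[rest] = (wr @ values) / wr.sum(axis=1)
    return out


def krige_surface(
    unit_table: pd.DataFrame,
    column: str,
    out_cell: float = 500.0,
    bounds: tuple[float, float, float, float] | None = None,
    nugget: float | None = 0.0,
) -> "LevelSurface":
    """Krige a unit-level column to a regular grid of ``out_cell`` meters.

    ``bounds`` is (xmin, ymin, xmax, ymax); by default the hull of the unit
    centroids padded by half a unit spacing.  Classification is left to
    :func:`classify_levels`.
    """
    pts = unit_table[["centroid_x", "centroid_y"]].to_numpy(float)
    vals = unit_table[column].to_numpy(float)
    if bounds is None:
        pad = out_cell
        bounds = (
            pts[:, 0].min() - pad, pts[:, 1].min() - pad,
            pts[:, 0].max() + pad, pts[:, 1].max() + pad,
        )
    xmin, ymin, xmax, ymax = bounds
    nx = max(int(np.ceil((xmax - xmin) / out_cell)), 1)
    ny = max(int(np.ceil((ymax - ymin) / out_cell)), 1)
    xs = xmin + (np.arange(nx) + 0.5) * out_cell
    ys = ymax - (np.arange(ny) + 0.5) * out_cell
    qx, qy = np.meshgrid(xs, ys)
    query = np.column_stack([qx.ravel(), qy.ravel()])
    field = krige(pts, vals, query, nugget=nugget).reshape(ny, nx)
    return LevelSurface(field=field, cell_size=out_cell, origin=(xmin, ymax))


@dataclass
class LevelSurface:
    """A kriged continuous field plus (after classification) its levels."""

    field: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    levels: np.ndarray | None = None
    thresholds: tuple[float, ...] | None = None

    @property
    def cell_area_hm2(self) -> float:
        return self.cell_size**2 / 10_000.0

    def area_table(self, labels: tuple[str, ...] = LEVEL_LABELS) -> pd.Series:
        if self.levels is None:
            raise ValueError("surface not classified yet")
        counts = np.bincount(self.levels.ravel(), minlength=len(labels))
        return pd.Series(
            counts * self.cell_area_hm2, index=list(labels), name="area_hm2"
        )


def classify_levels(
    surface: LevelSurface | np.ndarray,
    thresholds: tuple[float, ...] = DEFAULT_ERI_THRESHOLDS,
    labels: tuple[str, ...] = LEVEL_LABELS,
) -> LevelSurface:
    """Classify a continuous field into levels with half-open intervals.

    Breaks are lower-inclusive from the second level upward: a value equal
    to a break belongs to the higher level (0.0061 → II).  Raising a value
    can never lower its level.
    """
    t = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    if len(t) != len(labels) - 1:
        raise ValueError("need one fewer threshold than labels")
    if isinstance(surface, np.ndarray):
        surface = LevelSurface(field=surface, cell_size=500.0)
    lev = np.digitize(surface.field, t, right=False)
    return LevelSurface(
        field=surface.field,
        cell_size=surface.cell_size,
        origin=surface.origin,
        levels=lev,
        thresholds=tuple(t),
    )


def level_transfer(
    l1: LevelSurface, l2: LevelSurface, labels: tuple[str, ...] = LEVEL_LABELS
) -> pd.DataFrame:
    """Area matrix (hm²) of level changes between two classified surfaces."""
    if l1.levels is None or l2.levels is None:
        raise ValueError("both surfaces must be classified")
    if l1.field.shape != l2.field.shape or l1.cell_size != l2.cell_size:
        raise ValueError("surfaces are not on the same grid")
    k = len(labels)
    joint = np.bincount(
        l1.levels.ravel() * k + l2.levels.ravel(), minlength=k * k
    ).reshape(k, k)
    return pd.DataFrame(joint * l1.cell_area_hm2, index=list(labels), columns=list(labels))


# ---------------------------------------------------------------------------
# Global Moran's I


def contiguity_weights(
    positions: np.ndarray, scheme: str = "queen", spacing: float | None = None
) -> np.ndarray:
    """Row-standardized contiguity weights for points on a regular lattice.

    ``positions`` are (n, 2) coordinates; two points are neighbors when
    their offset is one lattice step (rook: orthogonal only; queen: also
    diagonal).  ``spacing`` defaults to the smallest nonzero coordinate
    difference.
    """
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    if spacing is None:
        dx = np.unique(np.abs(pos[:, 0][:, None] - pos[:, 0]))
        dy = np.unique(np.abs(pos[:, 1][:, None] - pos[:, 1]))
        cand = np.concatenate([dx[dx > 1e-9], dy[dy > 1e-9]])
        spacing = cand.min() if cand.size else 1.0
    gi = np.round((pos - pos.min(axis=0)) / spacing).astype(int)
    W = np.zeros((n, n))
    offs_rook = {(0, 1), (0, -1), (1, 0), (-1, 0)}
    offs_queen = offs_rook | {(1, 1), (1, -1), (-1, 1), (-1, -1)}
    offs = offs_queen if scheme == "queen" else offs_rook
    index = {tuple(g): i for i, g in enumerate(gi)}
    for i, g in enumerate(gi):
        for di, dj in offs:
            j = index.get((g[0] + di, g[1] + dj))
            if j is not None:
                W[i, j] = 1.0
    rs = W.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    return W / rs


def morans_i(
    values: np.ndarray,
    weights: np.ndarray,
    permutations: int = 999,
    seed: int | None = None,
) -> dict:
    """Global Moran's I with a permutation p-value.

    Returns ``{"I", "expected", "p_value"}`` where ``expected`` is the
    null expectation −1/(n−1) and ``p_value`` the one-sided (greater)
    pseudo p from ``permutations`` seeded random relabelings.
    """
    z = np.asarray(values, dtype=float)
    n = len(z)
    if n < 2 or np.ptp(z) == 0:
        raise ValueError("Moran's I needs >= 2 units with nonzero variance (constant field)")
    W = np.asarray(weights, dtype=float)
    z = z - z.mean()
    s0 = W.sum()
    denom = (z**2).sum()

    def stat(v: np.ndarray) -> float:
        return float((n / s0) * (v @ W @ v) / denom)

    i_obs = stat(z)
    rng = np.random.default_rng(seed)
    if permutations:
        sims = np.empty(permutations)
        for k in range(permutations):
            sims[k] = stat(rng.permutation(z))
        p = (1 + np.sum(sims >= i_obs)) / (permutations + 1)
    else:
        p = np.nan
    return {"I": i_obs, "expected": -1.0 / (n - 1), "p_value": float(p)}


def kmeans_breaks(values: np.ndarray, n_classes: int = 5, seed: int = 0) -> np.ndarray:
    """Optional 1-D k-means class breaks (natural-breaks style), off by
    default everywhere; the shipped thresholds are the canonical defaults."""
    from scipy.cluster.vq import kmeans2

    v = np.asarray(values, dtype=float).ravel()
    centers, lab = kmeans2(v[:, None], n_classes, seed=seed, minit="++")
    order = np.argsort(centers.ravel())
    sorted_vals = [np.sort(v[lab == o]) for o in order]
    breaks = []
    for a, b in zip(sorted_vals[:-1], sorted_vals[1:]):
        if len(a) and len(b):
            breaks.append((a[-1] + b[0]) / 2.0)
    return np.asarray(breaks)
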