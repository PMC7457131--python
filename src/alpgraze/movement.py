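"""Trajectory and pedometer summaries, grid occupancy, and habitat covariates.

GPS fixes (nominal 15 s interval) are reduced per cow and paddock to a mean
travel speed (m/h, with a jump filter for GPS outliers), and to occupancy
counts on a 5 x 5 m grid clipped to the paddock.  Evenness of space use is
Camargo's index over all grid cells inside the paddock, zero-count cells
included.  Two topographic covariates are attached to every cell — percent
slope (Horn eight-neighbour gradient of the DEM) and Euclidean distance to
the nearest accessible water point — and the per-individual occupancy counts
are regressed on each z-scored covariate with a Poisson log-linear model
(quasi-likelihood dispersion), giving standardized coefficients comparable
across paddocks and individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely import contains_xy
from shapely.geometry import Polygon

from .records import DegenerateDataError, PaddockGeometry, ValidationError

#: Default jump filter: a 15 s segment longer than this is a GPS error
#: (implied speed > 10 km/h).
DEFAULT_MAX_STEP_M = 10_000.0 / 3600.0 * 15.0


def track_speed(
    fixes: pd.DataFrame, max_step_m: float = DEFAULT_MAX_STEP_M
) -> tuple[float, float]:
    """Mean travel speed (m/h) and total distance (m) of one track.

    ``fixes`` needs columns t (s, strictly increasing), x, y (projected m).
    Inter-fix segments longer than ``max_step_m`` are dropped from the
    distance as GPS errors; elapsed time is the full first-to-last span.
    Pass ``max_step_m=np.inf`` to disable the filter.
    """
    if len(fixes) < 2:
        raise DegenerateDataError("need >= 2 fixes")
    t = fixes["t"].to_numpy(dtype=float)
    if (np.diff(t) <= 0).any():
        raise ValidationError("timestamps not strictly increasing")
    dx = np.diff(fixes["x"].to_numpy(dtype=float))
    dy = np.diff(fixes["y"].to_numpy(dtype=float))
    seg = np.hypot(dx, dy)
    dist = float(seg[seg <= max_step_m].sum())
    hours = (t[-1] - t[0]) / 3600.0
    return dist / hours, dist


def pedometer_summary(intervals: pd.DataFrame) -> tuple[float, float]:
    """(steps per hour, lying ratio) pooled over recording intervals.

    Needs columns duration_s, steps, lying_s; rates are duration-weighted
    (total steps / total hours, total lying / total time).
    """
    total_s = float(intervals["duration_s"].sum())
    if total_s <= 0:
        raise DegenerateDataError("zero total pedometer duration")
    steps_per_h = float(intervals["steps"].sum()) / (total_s / 3600.0)
    lying_ratio = float(intervals["lying_s"].sum()) / total_s
    return steps_per_h, lying_ratio


@dataclass
class OccupancyGrid:
    """Per-paddock occupancy grid with covariates.

    Arrays are indexed [row, col], row 0 at the south edge; the grid origin
    (x0, y0) is the lower-left corner of the paddock bounding box and cells
    are half-open: a fix at exactly a cell edge belongs to the
    higher-index cell.
    """

    paddock_id: str
    x0: float
    y0: float
    cell_size: float
    counts: np.ndarray        # int, fixes per cell (0 outside mask)
    slope_pct: np.ndarray     # percent slope at cell centers
    water_dist_m: np.ndarray  # distance to nearest water point
    mask: np.ndarray          # bool, cell center inside paddock
    n_outside: int            # fixes falling on unmasked cells / off-grid

    @property
    def n_inside(self) -> int:
        return int(self.counts[self.mask].sum())


def grid_shape(boundary: Polygon, cell_size: float) -> tuple[int, int, float, float]:
    minx, miny, maxx, maxy = boundary.bounds
    nx = int(np.ceil((maxx - minx) / cell_size))
    ny = int(np.ceil((maxy - miny) / cell_size))
    return ny, nx, minx, miny


def cell_centers(
    ny: int, nx: int, x0: float, y0: float, cell: float
) -> tuple[np.ndarray, np.ndarray]:
    cx = x0 + (np.arange(nx) + 0.5) * cell
    cy = y0 + (np.arange(ny) + 0.5) * cell
    return np.meshgrid(cx, cy)  # each (ny, nx)


def rasterize_fixes(
    fixes: pd.DataFrame, paddock: PaddockGeometry, cell_size: float = 5.0
) -> OccupancyGrid:
    """Count GPS fixes in half-open 5 x 5 m cells clipped to the paddock.

    Fixes on cells whose center lies outside the paddock polygon (or off
    the grid entirely) are tallied in ``n_outside``, never dropped
    silently; the masked counts conserve the number of inside fixes.
    """
    ny, nx, x0, y0 = grid_shape(paddock.boundary, cell_size)
    cxx, cyy = cell_centers(ny, nx, x0, y0, cell_size)
    mask = contains_xy(paddock.boundary, cxx, cyy)

    ix = np.floor((fixes["x"].to_numpy(dtype=float) - x0) / cell_size).astype(int)
    iy = np.floor((fixes["y"].to_numpy(dtype=float) - y0) / cell_size).astype(int)
    on_grid = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    inside = on_grid.copy()
    inside[on_grid] = mask[iy[on_grid], ix[on_grid]]

    counts = np.zeros((ny, nx), dtype=int)
    np.add.at(counts, (iy[inside], ix[inside]), 1)

    slope = sample_raster(
        slope_raster(paddock.dem, paddock.dem_cell),
        paddock.dem_x0, paddock.dem_y0, paddock.dem_cell, cxx, cyy,
    )
    wdist = water_distance(cxx, cyy, paddock.water_points)
    return OccupancyGrid(
        paddock_id=paddock.paddock_id,
        x0=x0, y0=y0, cell_size=cell_size,
        counts=counts, slope_pct=slope, water_dist_m=wdist,
        mask=mask, n_outside=int((~inside).sum()),
    )


def camargo_evenness(counts: np.ndarray) -> float:
    """Camargo's evenness of occupancy proportions across cells.

    E = 1 − Σ_{i<j} |p_i − p_j| / S with p_i the occupancy proportion of
    cell i and S the number of cells (zero-count cells inside the paddock
    are cells too).  Computed by a sorted prefix-sum identity equivalent to
    the pairwise enumeration:  for sorted p the pairwise sum is
    Σ_k p_(k) (2k − S + 1).  E = 1 for perfectly even use, → 0 for use
    concentrated in few of many cells.
    """
    c = np.asarray(counts, dtype=float).ravel()
    if c.size == 0:
        raise DegenerateDataError("no cells")
    if (c < 0).any():
        raise ValidationError("negative counts")
    total = c.sum()
    if total <= 0:
        raise DegenerateDataError("all-zero counts")
    p = np.sort(c / total)
    s = p.size
    k = np.arange(s)
    pairwise = float((p * (2 * k - s + 1)).sum())
    return 1.0 - pairwise / s


def slope_raster(dem: np.ndarray, cell: float) -> np.ndarray:
    """Percent slope (100·tan θ) from a DEM by Horn's eight-neighbour
    finite differences; edge cells replicate the nearest interior value."""
    z = np.asarray(dem, dtype=float)
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValidationError("DEM must be at least 3x3")
    zp = np.pad(z, 1, mode="edge")
    # Horn kernel: weights 1,2,1 along each edge of the 3x3 window
    gx = (
        (zp[:-2, 2:] + 2 * zp[1:-1, 2:] + zp[2:, 2:])
        - (zp[:-2, :-2] + 2 * zp[1:-1, :-2] + zp[2:, :-2])
    ) / (8.0 * cell)
    gy = (
        (zp[2:, :-2] + 2 * zp[2:, 1:-1] + zp[2:, 2:])
        - (zp[:-2, :-2] + 2 * zp[:-2, 1:-1] + zp[:-2, 2:])
    ) / (8.0 * cell)
    return 100.0 * np.hypot(gx, gy)


def sample_raster(
    values: np.ndarray, x0: float, y0: float, cell: float,
    xs: np.ndarray, ys: np.ndarray,
) -> np.ndarray:
    """Nearest-cell sampling of a raster at point coordinates."""
    ix = np.clip(((xs - x0) / cell).astype(int), 0, values.shape[1] - 1)
    iy = np.clip(((ys - y0) / cell).astype(int), 0, values.shape[0] - 1)
    return values[iy, ix]


def water_distance(
    xs: np.ndarray, ys: np.ndarray, water_points: tuple[tuple[float, float], ...]
) -> np.ndarray:
    """Minimum Euclidean distance (m) from each point to any water point."""
    if len(water_points) == 0:
        raise ValidationError("no water points")
    wp = np.asarray(water_points, dtype=float)
    d = np.hypot(
        xs[..., None] - wp[:, 0], ys[..., None] - wp[:, 1]
    )
    return d.min(axis=-1)


@dataclass
class CovariateEffect:
    covariate: str
    coef: float       # standardized (per SD of covariate) log-linear slope
    se: float         # quasi-Poisson standard error
    z_value: float
    dispersion: float
    n_cells: int
    converged: bool


def poisson_irls(
    X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Poisson log-linear fit by iteratively reweighted least squares.

    Returns (beta, unscaled covariance (X'WX)^-1, converged).
    """
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log(max(y.mean(), 1e-12))
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = np.exp(np.clip(eta, -30, 30))
        W = mu  # Poisson working weights
        z = eta + (y - mu) / mu
        XtW = X.T * W
        new = np.linalg.solve(XtW @ X, XtW @ z)
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            converged = True
            break
        beta = new
    eta = X @ beta
    mu = np.exp(np.clip(eta, -30, 30))
    cov = np.linalg.inv((X.T * mu) @ X)
    return beta, cov, converged


def covariate_effect(grid: OccupancyGrid, covariate: str) -> CovariateEffect:
    """Standardized effect of a habitat covariate on space use.

    Fits counts_i ~ Poisson(exp(a + b·z_i)) over the masked cells, z the
    z-scored covariate ("slope" or "water"), by IRLS.  The reported
    standard error is inflated by the Pearson-χ² dispersion
    (quasi-likelihood), a pragmatic stand-in for spatially structured
    extra-Poisson variation.  b < 0 means the covariate repels use.
    """
    if covariate == "slope":
        raw = grid.slope_pct[grid.mask]
    elif covariate == "water":
        raw = grid.water_dist_m[grid.mask]
    else:
        raise ValueError(f"unknown covariate {covariate!r}")
    y = grid.counts[grid.mask].astype(float)
    if y.size < 10:
        raise DegenerateDataError(f"only {y.size} masked cells; need >= 10")
    sd = raw.std()
    if sd <= 0:
        raise DegenerateDataError(f"covariate {covariate!r} is constant")
    zc = (raw - raw.mean()) / sd
    X = np.column_stack([np.ones_like(zc), zc])
    beta, cov, converged = poisson_irls(X, y)
    if not converged:
        raise DegenerateDataError("IRLS did not converge in 100 iterations")
    mu = np.exp(X @ beta)
    pearson = float(((y - mu) ** 2 / mu).sum())
    dispersion = max(pearson / (y.size - 2), 1.0)
    se = float(np.sqrt(cov[1, 1] * dispersion))
    return CovariateEffect(
        covariate=covariate,
        coef=float(beta[1]),
        se=se,
        z_value=float(beta[1] / se),
        dispersion=dispersion,
        n_cells=int(y.size),
        converged=converged,
    )


def movement_metrics(
    fixes: pd.DataFrame,
    pedometer: pd.DataFrame | None,
    paddock: PaddockGeometry,
    cell_size: float = 5.0,
    max_step_m: float = DEFAULT_MAX_STEP_M,
) -> dict:
    """All movement summaries for one cow on one paddock.

    Returns a flat dict: speed_m_h, distance_m, steps_per_h, lying_ratio
    (NaN without pedometer data), camargo_evenness, slope_coef, water_coef,
    n_fixes, n_outside.
    """
    speed, dist = track_speed(fixes, max_step_m=max_step_m)
    grid = rasterize_fixes(fixes, paddock, cell_size=cell_size)
    evenness = camargo_evenness(grid.counts[grid.mask])
    out = {
        "speed_m_h": speed,
        "distance_m": dist,
        "camargo_evenness": evenness,
        "n_fixes": len(fixes),
        "n_outside": grid.n_outside,
    }
    for cov_name, key in (("slope", "slope_coef"), ("water", "water_coef")):
        try:
            out[key] = covariate_effect(grid, cov_name).coef
        except DegenerateDataError:
            out[key] = float("nan")
    if pedometer is not None and len(pedometer):
        steps_per_h, lying_ratio = pedometer_summary(pedometer)
        out["steps_per_h"] = steps_per_h
        out["lying_ratio"] = lying_ratio
    else:
        out["steps_per_h"] = float("nan")
        out["lying_ratio"] = float("nan")
    return out
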