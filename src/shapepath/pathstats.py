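"""Projected-path and angular-coordination statistics for migrating cells.

A migrating neuron that leaves an aggregate tends to keep moving outward.
The reference direction it is "expected to follow" — the projected path —
is estimated from the first half of its trajectory by robust linear
regression (Tukey bisquare weights), so that a few gross positional
outliers cannot tilt the reference line.  Against that reference, three
per-frame angles quantify how tightly cell shape and movement are
coordinated:

* ``axis rotation`` — fitted-ellipse major-axis orientation minus the path
  heading, folded to [-90, 90) because an axis has no head;
* ``turning angle`` — movement-vector heading minus the path heading,
  wrapped to (-180, 180];
* ``accordance angle`` — movement-vector heading minus the major-axis
  orientation, folded to [-90, 90).

The joint (rotation, turning) distribution is summarised by a bivariate
Gaussian kernel density (default bandwidth 20 deg per dimension) on a
1-degree grid, renormalised so its trapezoidal integral is one; its
maximum is the ``peak probability density`` in units of per degree
squared.  The ``accordance rate`` is the fraction of frames whose
accordance angle lies strictly inside +/-15 deg.

All positions are in image coordinates (x right, y down); angles are
converted to the standard mathematical convention (counterclockwise from
+x with y up) by negating dy, and that convention is used consistently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ProjectedPath",
    "AngleRecord",
    "DensitySurface",
    "fold_axis_deg",
    "wrap_signed_deg",
    "heading_deg",
    "fit_projected_path",
    "axis_rotation",
    "turning_angle",
    "accordance_angle",
    "compute_angles",
    "kde_surface",
    "bivariate_density",
    "peak_density",
    "accordance_rate",
]

#: default evaluation grids, one-degree steps
ROTATION_GRID = np.arange(-90.0, 90.0 + 0.5, 1.0)
TURNING_GRID = np.arange(-180.0, 180.0 + 0.5, 1.0)

DEFAULT_BANDWIDTH_DEG = 20.0
DEFAULT_HALF_WIDTH_DEG = 15.0
#: movement shorter than this (px/frame) counts as a stationary frame
MIN_STEP_PX = 1e-9


def fold_axis_deg(deg):
    """Fold a 180-degree-periodic (headless axis) angle into [-90, 90)."""
    return (np.asarray(deg, dtype=float) + 90.0) % 180.0 - 90.0


def wrap_signed_deg(deg):
    """Wrap an angle into (-180, 180]."""
    return -((-np.asarray(deg, dtype=float) + 180.0) % 360.0 - 180.0)


def heading_deg(vec):
    """Heading of displacement vector(s) given in image coordinates.

    ``vec`` has shape (..., 2) holding (dx, dy) with y pointing down; the
    returned heading is counterclockwise from +x in math convention
    (y up), in (-180, 180].
    """
    v = np.asarray(vec, dtype=float)
    return np.degrees(np.arctan2(-v[..., 1], v[..., 0]))


class DegeneratePathError(ValueError):
    """All first-half positions coincide; no direction can be defined."""


@dataclass
class ProjectedPath:
    """Robust-fit reference line for one cell.

    ``direction`` is a unit vector in image coordinates (dx, dy), signed so
    that it points along the cell's net first-half displacement.
    """

    cell_id: object
    direction: np.ndarray
    anchor: np.ndarray
    n_points_used: int
    robust_scale: float
    n_iter: int = 0
    fit_window_h: tuple = (42.0, 47.75)

    @property
    def heading(self) -> float:
        """Path heading in degrees, math convention (y up)."""
        return float(heading_deg(self.direction))


def _theil_sen_start(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Median-of-pairwise-slopes line, the IRLS starting point.

    Falls back to ordinary least squares for very long inputs where the
    quadratic pair count would dominate the cost.
    """
    n = x.size
    X = np.column_stack([np.ones_like(x), x])
    if n > 2000:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return beta
    i, j = np.triu_indices(n, k=1)
    dx = x[j] - x[i]
    keep = np.abs(dx) > 1e-12
    if not keep.any():
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return beta
    slope = float(np.median((y[j] - y[i])[keep] / dx[keep]))
    intercept = float(np.median(y - slope * x))
    return np.array([intercept, slope])


def _mad_scale(residuals: np.ndarray) -> float:
    r = np.asarray(residuals, dtype=float)
    return 1.4826 * float(np.median(np.abs(r - np.median(r))))


def fit_projected_path(
    points,
    cell_id=None,
    tuning: float = 4.685,
    max_iter: int = 50,
    tol: float = 1e-8,
    fit_window_h: tuple = (42.0, 47.75),
) -> ProjectedPath:
    """Fit the projected path by IRLS with Tukey bisquare weights.

    The coordinate with the larger variance is used as the regressor so
    near-vertical paths do not degenerate.  Scale is re-estimated each
    iteration as 1.4826 x the median absolute deviation of the residuals;
    an (almost) exact linear fit short-circuits to ordinary least squares.

    Parameters
    ----------
    points : (n, 2) array
        First-half smoothed positions in image coordinates; n >= 5.

    Raises
    ------
    ValueError
        Fewer than 5 points.
    DegeneratePathError
        All points identical.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must have shape (n, 2)")
    if pts.shape[0] < 5:
        raise ValueError(f"projected path needs >= 5 points, got {pts.shape[0]}")
    span = pts.max(axis=0) - pts.min(axis=0)
    scale0 = float(np.max(span))
    if scale0 < 1e-12:
        raise DegeneratePathError("all points identical; no path direction")

    var = pts.var(axis=0)
    swap = var[1] > var[0]
    x = pts[:, 1] if swap else pts[:, 0]
    y = pts[:, 0] if swap else pts[:, 1]
    X = np.column_stack([np.ones_like(x), x])

    # A redescending bisquare loss has local optima, and a gross outlier can
    # act as a leverage point for the chosen regressor; a high-breakdown
    # Theil-Sen start keeps the IRLS in the right basin.
    beta = _theil_sen_start(x, y)
    scale = 0.0
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        r = y - X @ beta
        scale = _mad_scale(r)
        if scale < 1e-10 * (1.0 + scale0):
            break  # essentially exact fit
        u = r / (tuning * scale)
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        if w.sum() <= 0:
            break
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        converged = np.max(np.abs(beta_new - beta)) < tol * (1.0 + np.max(np.abs(beta)))
        beta = beta_new
        if converged:
            break

    slope = beta[1]
    d = np.array([slope, 1.0]) if swap else np.array([1.0, slope])
    d = d / np.linalg.norm(d)
    net = pts[-1] - pts[0]
    if float(d @ net) < 0:
        d = -d
    xbar = float(x.mean())
    yhat = float(beta[0] + beta[1] * xbar)
    anchor = np.array([yhat, xbar]) if swap else np.array([xbar, yhat])
    return ProjectedPath(
        cell_id=cell_id,
        direction=d,
        anchor=anchor,
        n_points_used=pts.shape[0],
        robust_scale=float(scale),
        n_iter=n_iter,
        fit_window_h=tuple(fit_window_h),
    )


def axis_rotation(orientation_deg, path: ProjectedPath):
    """Major-axis orientation relative to the path, folded to [-90, 90)."""
    return fold_axis_deg(np.asarray(orientation_deg, dtype=float) - path.heading)


def turning_angle(movement_vec, path: ProjectedPath):
    """Signed angle from the path direction to the movement vector.

    Wrapped to (-180, 180]; raises on a zero movement vector (stationary
    frames carry no heading and are flagged invalid upstream).
    """
    v = np.asarray(movement_vec, dtype=float)
    if np.linalg.norm(v) <= MIN_STEP_PX:
        raise ValueError("zero movement vector has no turning angle")
    return float(wrap_signed_deg(heading_deg(v) - path.heading))


def accordance_angle(movement_vec, orientation_deg):
    """Headless difference between movement heading and axis orientation.

    Folded to [-90, 90); raises on a zero movement vector.
    """
    v = np.asarray(movement_vec, dtype=float)
    if np.linalg.norm(v) <= MIN_STEP_PX:
        raise ValueError("zero movement vector has no accordance angle")
    return float(fold_axis_deg(heading_deg(v) - float(orientation_deg)))


@dataclass
class AngleRecord:
    """Per-frame angular statistics for one cell, relative to its path."""

    cell_id: object
    frame: int
    time_h: float
    rotation_deg: float
    turning_deg: float
    accordance_deg: float
    valid: bool


def compute_angles(
    trajectory,
    orientations_by_frame: dict,
    path: ProjectedPath,
    window_h: tuple = (48.0, 54.0),
) -> list:
    """Build per-frame AngleRecords inside the analysis window.

    ``orientations_by_frame`` maps frame index to the fitted major-axis
    orientation (degrees) or ``None`` when the frame was excluded by shape
    QC.  A record is valid only when the frame lies in ``window_h``, the
    movement vector is nonzero and an orientation is available; invalid
    records carry NaN angles and never enter downstream statistics.
    """
    lo, hi = window_h
    out = []
    frames = np.asarray(trajectory.frames)
    for k in range(len(frames) - 1):  # movement vector k spans frames k -> k+1
        t = float(trajectory.times_h[k])
        if not (lo <= t <= hi):
            continue
        v = trajectory.movement_vec[k]
        ori = orientations_by_frame.get(int(frames[k]))
        moving = float(np.linalg.norm(v)) > MIN_STEP_PX
        if moving and ori is not None and np.isfinite(ori):
            rec = AngleRecord(
                cell_id=trajectory.cell_id,
                frame=int(frames[k]),
                time_h=t,
                rotation_deg=float(axis_rotation(ori, path)),
                turning_deg=turning_angle(v, path),
                accordance_deg=accordance_angle(v, ori),
                valid=True,
            )
        else:
            rec = AngleRecord(
                cell_id=trajectory.cell_id,
                frame=int(frames[k]),
                time_h=t,
                rotation_deg=np.nan,
                turning_deg=np.nan,
                accordance_deg=np.nan,
                valid=False,
            )
        out.append(rec)
    return out


@dataclass
class DensitySurface:
    """Bivariate probability density over (rotation, turning), per degree^2."""

    grid_rotation: np.ndarray
    grid_turning: np.ndarray
    density: np.ndarray  # shape (len(grid_rotation), len(grid_turning))
    bandwidth_deg: float
    n_records: int = 0

    def integral(self) -> float:
        inner = np.trapezoid(self.density, self.grid_turning, axis=1)
        return float(np.trapezoid(inner, self.grid_rotation))

    def peak(self) -> float:
        return float(self.density.max())


def _gauss_kernel_matrix(grid: np.ndarray, samples: np.ndarray, h: float) -> np.ndarray:
    z = (grid[:, None] - samples[None, :]) / h
    return np.exp(-0.5 * z * z) / (h * np.sqrt(2.0 * np.pi))


def kde_surface(
    rotation_deg,
    turning_deg,
    bandwidth_deg: float = DEFAULT_BANDWIDTH_DEG,
    grid_rotation: np.ndarray = None,
    grid_turning: np.ndarray = None,
) -> DensitySurface:
    """Product-Gaussian KDE of (rotation, turning) samples on a 1-deg grid.

    A plain (non-periodic) kernel smoother; mass lost past the grid edges
    is corrected by renormalising so the trapezoidal grid integral is one.
    """
    rot = np.asarray(rotation_deg, dtype=float).ravel()
    turn = np.asarray(turning_deg, dtype=float).ravel()
    if rot.size != turn.size:
        raise ValueError("rotation and turning sample arrays differ in length")
    if rot.size == 0:
        raise ValueError("no samples")
    gr = ROTATION_GRID if grid_rotation is None else np.asarray(grid_rotation, float)
    gt = TURNING_GRID if grid_turning is None else np.asarray(grid_turning, float)
    A = _gauss_kernel_matrix(gr, rot, bandwidth_deg)
    B = _gauss_kernel_matrix(gt, turn, bandwidth_deg)
    dens = (A @ B.T) / rot.size
    surf = DensitySurface(gr, gt, dens, float(bandwidth_deg), n_records=rot.size)
    total = surf.integral()
    if total <= 0:
        raise ValueError("degenerate density (zero integral)")
    surf.density = dens / total
    return surf


def bivariate_density(
    records: Iterable[AngleRecord],
    bandwidth_deg: float = DEFAULT_BANDWIDTH_DEG,
) -> DensitySurface:
    """KDE over the valid records' (rotation, turning) pairs.

    Requires at least 10 valid records; invalid (stationary / QC-excluded)
    records are ignored.
    """
    recs = [r for r in records if r.valid]
    if len(recs) < 10:
        raise ValueError(f"need >= 10 valid records, got {len(recs)}")
    rot = np.array([r.rotation_deg for r in recs])
    turn = np.array([r.turning_deg for r in recs])
    return kde_surface(rot, turn, bandwidth_deg)


def peak_density(surface: DensitySurface) -> float:
    """Maximum of the density surface, per degree squared."""
    return surface.peak()


def accordance_rate(
    records,
    half_width_deg: float = DEFAULT_HALF_WIDTH_DEG,
) -> float:
    """Fraction of valid records with |accordance| strictly below the bound.

    ``records`` may be AngleRecords or a bare array of accordance angles in
    degrees.  The denominator counts valid records only.
    """
    if len(records) and isinstance(records[0], AngleRecord):
        vals = np.array([r.accordance_deg for r in records if r.valid])
    else:
        vals = np.asarray(records, dtype=float)
        vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no valid records")
    return float(np.mean(np.abs(vals) < half_width_deg))
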