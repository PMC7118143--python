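"""Cell-body segmentation and moments-equivalent ellipse profiling.

For each tracked cell and frame, a window is cut out of the
phase-contrast image around the nucleus, cell outlines are detected with
a Sobel gradient filter, the outline is closed morphologically
(dilation then erosion, then hole filling) and the connected component
belonging to the tracked nucleus is selected.  That object is profiled
as the ellipse with the same normalized second central moments: full
axis lengths are 4 x sqrt(eigenvalue) of the 2x2 second-central-moment
matrix, eccentricity is the inter-focal distance over the major axis
length, and solidity is the object's pixel count over its convex hull's.
Crescent-shaped misidentifications are excluded by a solidity threshold
(strictly below 0.7 is rejected).

Coordinates are 0-based pixel indices with pixel-centre continuous
centroids; orientations are reported counterclockwise from +x with the
image y-axis flipped, folded into [-90, 90).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.filters import sobel, threshold_otsu
from skimage.measure import label
from skimage.morphology import convex_hull_image, disk

__all__ = [
    "EllipseFit",
    "SegmentationConfig",
    "crop_around_nucleus",
    "detect_edges",
    "close_object",
    "select_cell_body",
    "fit_ellipse",
    "eccentricity_of",
    "qc_filter",
    "profile_frame",
    "segment_positions",
]


@dataclass
class EllipseFit:
    """Fitted cell-body ellipse for one frame (lengths in pixels)."""

    frame_index: int
    centroid_x: float
    centroid_y: float
    area_px: int
    major_px: float
    minor_px: float
    orientation_deg: float
    eccentricity: float
    solidity: float
    excluded: bool = False
    reason: str = ""


@dataclass
class SegmentationConfig:
    crop_size: int = 244
    gradient_threshold_method: str | float = "otsu"
    closing_radius_px: int = 2
    solidity_threshold: float = 0.7
    min_area_px: int = 10
    nucleus_gate_px: float = 10.0
    # erosion applied to the selected object after hole filling; compensates
    # the finite width of the thresholded gradient band so segmented areas
    # are unbiased for the rendered-ellipse model (see docs/methods.md)
    boundary_erosion_px: int = 1

    def __post_init__(self):
        if not 0 < self.solidity_threshold < 1:
            raise ValueError("solidity_threshold must be in (0, 1)")
        if self.crop_size < 16:
            raise ValueError("crop_size must be >= 16")


def crop_around_nucleus(phase_frame, nucleus_xy, crop_size: int = 244):
    """Cut a crop_size x crop_size window centred on the nucleus.

    The window is clamped at the frame borders; the returned offset
    (x0, y0) maps crop coordinates back into frame coordinates.
    """
    img = np.asarray(phase_frame)
    h, w = img.shape
    if crop_size > min(h, w):
        raise ValueError(f"crop_size {crop_size} exceeds frame {img.shape}")
    cx, cy = float(nucleus_xy[0]), float(nucleus_xy[1])
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError(f"nucleus {nucleus_xy} outside frame {img.shape}")
    x0 = int(round(cx)) - crop_size // 2
    y0 = int(round(cy)) - crop_size // 2
    x0 = min(max(x0, 0), w - crop_size)
    y0 = min(max(y0, 0), h - crop_size)
    return img[y0 : y0 + crop_size, x0 : x0 + crop_size], (x0, y0)


def detect_edges(crop, threshold_method="otsu") -> np.ndarray:
    """Binary edge mask from the Sobel gradient magnitude.

    Otsu's method on the gradient image picks the threshold by default; a
    float threshold may be supplied instead.  A constant image yields an
    empty mask.
    """
    img = np.asarray(crop, dtype=float)
    g = sobel(img)
    if g.max() <= 0:
        return np.zeros_like(g, dtype=bool)
    if threshold_method == "otsu":
        thr = threshold_otsu(g)
    else:
        thr = float(threshold_method)
    return g > thr


def close_object(edge_mask, closing_radius_px: int = 2) -> np.ndarray:
    """Morphological closing with a disk, then hole filling."""
    mask = np.asarray(edge_mask, dtype=bool)
    if closing_radius_px > 0:
        r = closing_radius_px
        padded = np.pad(mask, r)  # avoid border clipping of the dilation
        padded = ndimage.binary_closing(padded, structure=disk(r))
        mask = padded[r:-r, r:-r]
    return ndimage.binary_fill_holes(mask)


def select_cell_body(
    object_mask,
    nucleus_xy,
    min_area_px: int = 10,
    nucleus_gate_px: float = 10.0,
) -> np.ndarray | None:
    """Pick the connected component belonging to the tracked nucleus.

    The component containing the nucleus position wins regardless of size;
    otherwise the nearest component whose boundary lies within the gate is
    taken.  Components below ``min_area_px`` are ignored.  Returns ``None``
    when no component qualifies.
    """
    mask = np.asarray(object_mask, dtype=bool)
    labels, n = label(mask, return_num=True)
    if n == 0:
        return None
    sizes = np.bincount(labels.ravel())
    candidates = [i for i in range(1, n + 1) if sizes[i] >= min_area_px]
    if not candidates:
        return None
    cx, cy = float(nucleus_xy[0]), float(nucleus_xy[1])
    ix, iy = int(round(cx)), int(round(cy))
    h, w = mask.shape
    if 0 <= iy < h and 0 <= ix < w:
        inside = labels[iy, ix]
        if inside in candidates:
            return labels == inside
    best, best_d = None, np.inf
    for i in candidates:
        ys, xs = np.nonzero(labels == i)
        d = float(np.min(np.hypot(xs - cx, ys - cy)))
        if d < best_d:
            best, best_d = i, d
    if best is None or best_d > nucleus_gate_px:
        return None
    return labels == best


def eccentricity_of(minor_px: float, major_px: float) -> float:
    """Inter-focal distance over major axis length: sqrt(1 - (b/a)^2).

    0 for a perfect circle, approaching 1 for a line segment.
    """
    if minor_px > major_px:
        raise ValueError("minor axis exceeds major axis")
    if major_px <= 0:
        raise ValueError("major axis must be positive")
    return float(np.sqrt(1.0 - (minor_px / major_px) ** 2))


def fit_ellipse(single_object_mask, frame_index: int = 0) -> EllipseFit:
    """Moments-equivalent ellipse of a binary object.

    The centroid is the pixel-coordinate mean; axes and orientation come
    from the eigendecomposition of the 2x2 normalized second central
    moment matrix (full axis lengths = 4 sqrt(eigenvalue)).  The moment
    cross-term is sign-flipped so the orientation follows the math
    convention (counterclockwise from +x, y up).  A degenerate (collinear)
    object gets minor axis 0 and is flagged excluded.
    """
    mask = np.asarray(single_object_mask, dtype=bool)
    ys, xs = np.nonzero(mask)
    if xs.size == 0:
        raise ValueError("empty mask")
    cx, cy = float(xs.mean()), float(ys.mean())
    dx = xs - cx
    dy = -(ys - cy)  # flip to math orientation (y up)
    mu20 = float(np.mean(dx * dx))
    mu02 = float(np.mean(dy * dy))
    mu11 = float(np.mean(dx * dy))
    common = 0.5 * (mu20 + mu02)
    diff = 0.5 * (mu20 - mu02)
    rad = float(np.hypot(diff, mu11))
    lam1 = max(common + rad, 0.0)
    lam2 = max(common - rad, 0.0)
    major = 4.0 * np.sqrt(lam1)
    minor = 4.0 * np.sqrt(lam2)
    if rad < 1e-15:
        orientation = 0.0  # isotropic: orientation undefined, report 0
    else:
        orientation = float(np.degrees(0.5 * np.arctan2(2.0 * mu11, mu20 - mu02)))
    from .pathstats import fold_axis_deg

    orientation = float(fold_axis_deg(orientation))
    area = int(xs.size)
    hull_area = int(convex_hull_image(mask).sum()) if area >= 3 else area
    solidity = area / hull_area if hull_area > 0 else 1.0
    if minor <= 1e-9:
        return EllipseFit(
            frame_index, cx, cy, area, major, 0.0, orientation, 1.0,
            solidity, excluded=True, reason="degenerate",
        )
    return EllipseFit(
        frame_index,
        cx,
        cy,
        area,
        major,
        minor,
        orientation,
        eccentricity_of(minor, major),
        solidity,
    )


def qc_filter(fit: EllipseFit, solidity_threshold: float = 0.7) -> EllipseFit:
    """Exclude crescent-shaped misidentifications by solidity.

    Objects strictly below the threshold are flagged ``low-solidity``; a
    solidity exactly at the threshold is retained.
    """
    if not fit.excluded and fit.solidity < solidity_threshold:
        return replace(fit, excluded=True, reason="low-solidity")
    return fit


def profile_frame(
    phase_frame,
    nucleus_xy,
    config: SegmentationConfig | None = None,
    frame_index: int = 0,
    manual_excluded: bool = False,
) -> EllipseFit:
    """Full single-frame chain: crop, edges, close, select, fit, QC.

    Centroid coordinates are mapped back into frame space.  Frames with no
    qualifying object are returned as excluded (reason ``no-object``);
    ``manual_excluded`` honours an optional by-eye exclusion list.
    """
    cfg = config or SegmentationConfig()
    crop, (x0, y0) = crop_around_nucleus(phase_frame, nucleus_xy, cfg.crop_size)
    local = (float(nucleus_xy[0]) - x0, float(nucleus_xy[1]) - y0)
    edges = detect_edges(crop, cfg.gradient_threshold_method)
    closed = close_object(edges, cfg.closing_radius_px)
    obj = select_cell_body(closed, local, cfg.min_area_px, cfg.nucleus_gate_px)
    if obj is None:
        return EllipseFit(
            frame_index, float(nucleus_xy[0]), float(nucleus_xy[1]),
            0, 0.0, 0.0, 0.0, 1.0, 1.0, excluded=True, reason="no-object",
        )
    if cfg.boundary_erosion_px > 0:
        eroded = ndimage.binary_erosion(obj, structure=disk(cfg.boundary_erosion_px))
        if eroded.sum() >= cfg.min_area_px:
            obj = eroded
    fit = fit_ellipse(obj, frame_index)
    fit = qc_filter(fit, cfg.solidity_threshold)
    fit = replace(fit, centroid_x=fit.centroid_x + x0, centroid_y=fit.centroid_y + y0)
    if manual_excluded and not fit.excluded:
        fit = replace(fit, excluded=True, reason="manual")
    return fit


def segment_positions(
    phase_frames,
    positions_df,
    config: SegmentationConfig | None = None,
    manual_exclusions=None,
    t0_h: float = 42.0,
    dt_h: float = 0.25,
):
    """Profile every (cell, frame) row of a positions table.

    ``phase_frames`` is a sequence indexed by frame; ``positions_df`` needs
    columns ``cell_id, frame, x, y``.  ``manual_exclusions`` is an optional
    set of (cell_id, frame) pairs.  Returns a tidy DataFrame, one row per
    (cell, frame), with the CSV dialect used throughout the pipeline.
    """
    import pandas as pd

    cfg = config or SegmentationConfig()
    manual = set(map(tuple, manual_exclusions)) if manual_exclusions is not None else set()
    rows = []
    for _, r in positions_df.sort_values(["cell_id", "frame"]).iterrows():
        f = int(r["frame"])
        fit = profile_frame(
            phase_frames[f],
            (float(r["x"]), float(r["y"])),
            cfg,
            frame_index=f,
            manual_excluded=(r["cell_id"], f) in manual,
        )
        rows.append(
            {
                "cell_id": r["cell_id"],
                "frame": f,
                "time_h": t0_h + dt_h * f,
                "centroid_x": fit.centroid_x,
                "centroid_y": fit.centroid_y,
                "area_px": fit.area_px,
                "major_px": fit.major_px,
                "minor_px": fit.minor_px,
                "orientation_deg": fit.orientation_deg,
                "eccentricity": fit.eccentricity,
                "solidity": fit.solidity,
                "excluded": fit.excluded,
                "reason": fit.reason,
            }
        )
    return pd.DataFrame(rows)
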