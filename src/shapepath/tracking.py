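"""Nucleus detection, frame-to-frame linking and position smoothing.

Cells are traced through the nuclear-fluorescence channel: bright nuclear
blobs are detected per frame, then linked across frames by gated
mutual-nearest-neighbour matching (no gap closing — sparse, slowly moving
cells do not need more).  Raw positions are smoothed with a centred
five-point moving average and differentiated by forward differences to
give per-frame movement vectors.

Frame 0 corresponds to t = 42 h after plating; frames are 0.25 h apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "TrackingConfig",
    "Trajectory",
    "detect_nuclei",
    "link_tracks",
    "smooth_positions",
    "movement_vectors",
    "trajectories_from_positions",
]

T0_H = 42.0
DT_H = 0.25


@dataclass
class TrackingConfig:
    gfp_threshold_method: str = "robust"
    max_link_px: float = 15.0
    smooth_window: int = 5
    min_track_frames: int = 40
    min_blob_px: int = 4
    distance_band_px: tuple | None = None  # optional (min, max) from aggregate edge

    def __post_init__(self):
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd and >= 1")
        if self.max_link_px <= 0:
            raise ValueError("max_link_px must be positive")


def smooth_positions(raw_xy, window: int = 5) -> np.ndarray:
    """Centred moving average per coordinate.

    Near the track ends the window shrinks symmetrically, which preserves
    track length and leaves affine (straight, constant-speed) tracks
    unchanged everywhere.
    """
    pts = np.asarray(raw_xy, dtype=float)
    n = pts.shape[0]
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window > n:
        raise ValueError(f"window {window} exceeds track length {n}")
    half = window // 2
    out = np.empty_like(pts)
    for i in range(n):
        k = min(i, n - 1 - i, half)
        out[i] = pts[i - k : i + k + 1].mean(axis=0)
    return out


def movement_vectors(smooth_xy) -> np.ndarray:
    """Forward differences of positions between adjacent frames."""
    pts = np.asarray(smooth_xy, dtype=float)
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 positions")
    return np.diff(pts, axis=0)


@dataclass
class Trajectory:
    """One cell's time-ordered positions with smoothed path and vectors."""

    cell_id: object
    frames: np.ndarray
    times_h: np.ndarray
    raw_xy: np.ndarray
    smooth_xy: np.ndarray
    movement_vec: np.ndarray

    @classmethod
    def from_raw(
        cls,
        cell_id,
        frames,
        raw_xy,
        smooth_window: int = 5,
        t0_h: float = T0_H,
        dt_h: float = DT_H,
    ) -> "Trajectory":
        frames = np.asarray(frames, dtype=int)
        raw = np.asarray(raw_xy, dtype=float)
        n = raw.shape[0]
        w = min(smooth_window, n if n % 2 == 1 else n - 1)  # short tracks shrink
        sm = smooth_positions(raw, max(w, 1))
        return cls(
            cell_id=cell_id,
            frames=frames,
            times_h=t0_h + dt_h * frames.astype(float),
            raw_xy=raw,
            smooth_xy=sm,
            movement_vec=movement_vectors(sm) if n >= 2 else np.empty((0, 2)),
        )

    def positions_in_window(self, window_h, smoothed: bool = True) -> np.ndarray:
        lo, hi = window_h
        sel = (self.times_h >= lo) & (self.times_h <= hi)
        return (self.smooth_xy if smoothed else self.raw_xy)[sel]


def detect_nuclei(gfp_frame, threshold_method="robust", min_blob_px: int = 4) -> np.ndarray:
    """Intensity-weighted centroids of above-threshold nuclear blobs.

    Returns an (n, 2) array of (x, y) positions; empty for a blank frame.
    ``threshold_method`` is ``"robust"`` (median + 6 MAD-sigmas of the
    frame, suited to sparse bright blobs on a noisy background), ``"otsu"``,
    or an absolute intensity value.
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import label, regionprops

    img = np.asarray(gfp_frame, dtype=float)
    if img.max() == img.min():
        return np.empty((0, 2))
    if threshold_method == "robust":
        med = np.median(img)
        sigma = 1.4826 * np.median(np.abs(img - med))
        thr = med + 6.0 * max(sigma, 1e-6)
        if thr >= img.max():  # noise-free background: fall back to midpoint
            thr = 0.5 * (img.max() + img.min())
    elif threshold_method == "otsu":
        thr = threshold_otsu(img)
    else:
        thr = float(threshold_method)
    mask = img > thr
    out = []
    for rp in regionprops(label(mask), intensity_image=img):
        if rp.area < min_blob_px:
            continue
        cy, cx = rp.centroid_weighted
        out.append((cx, cy))
    if not out:
        return np.empty((0, 2))
    return np.array(sorted(out))  # deterministic order (by x, then y)


def link_tracks(
    per_frame_centroids,
    max_link_px: float = 15.0,
    min_track_frames: int = 40,
    smooth_window: int = 5,
    t0_h: float = T0_H,
    dt_h: float = DT_H,
) -> list:
    """Link detections into trajectories by gated mutual nearest neighbours.

    ``per_frame_centroids`` is a sequence (index = frame) of (n, 2) arrays.
    A detection extends a track only if it is the nearest detection to the
    track's last position AND the track is the nearest track to it, within
    ``max_link_px``, in the immediately following frame; otherwise the
    track is closed (no gap closing) and the detection seeds a new track.
    Tracks shorter than ``min_track_frames`` are discarded.
    """
    open_tracks = []  # dicts: frames, xy, last_frame
    done = []
    for f, dets in enumerate(per_frame_centroids):
        dets = np.asarray(dets, dtype=float).reshape(-1, 2)
        active = [t for t in open_tracks if t["last_frame"] == f - 1]
        stale = [t for t in open_tracks if t["last_frame"] < f - 1]
        done.extend(stale)
        open_tracks = active
        matched_tracks, matched_dets = set(), set()
        if active and len(dets):
            last = np.array([t["xy"][-1] for t in active])
            D = cdist(last, dets)
            ti = np.argmin(D, axis=0)  # nearest track per detection
            dj = np.argmin(D, axis=1)  # nearest detection per track
            for i, t in enumerate(active):
                j = dj[i]
                if ti[j] == i and D[i, j] <= max_link_px:
                    t["frames"].append(f)
                    t["xy"].append(dets[j])
                    t["last_frame"] = f
                    matched_tracks.add(i)
                    matched_dets.add(int(j))
        for j in range(len(dets)):
            if j not in matched_dets:
                open_tracks.append(
                    {"frames": [f], "xy": [dets[j]], "last_frame": f}
                )
    done.extend(open_tracks)
    trajectories = []
    cid = 0
    for t in done:
        if len(t["frames"]) < max(min_track_frames, 1):
            continue
        trajectories.append(
            Trajectory.from_raw(
                cid, t["frames"], np.array(t["xy"]), smooth_window, t0_h, dt_h
            )
        )
        cid += 1
    return trajectories


def trajectories_from_positions(
    positions_df,
    smooth_window: int = 5,
    min_track_frames: int = 2,
    t0_h: float = T0_H,
    dt_h: float = DT_H,
) -> list:
    """Build trajectories from a precomputed positions table.

    Bypasses detection/linking; the table needs columns
    ``cell_id, frame, x, y`` (the ground-truth CSV dialect).
    """
    out = []
    for cid, grp in positions_df.groupby("cell_id", sort=True):
        grp = grp.sort_values("frame")
        if len(grp) < max(min_track_frames, smooth_window, 2):
            continue
        out.append(
            Trajectory.from_raw(
                cid,
                grp["frame"].to_numpy(),
                grp[["x", "y"]].to_numpy(dtype=float),
                smooth_window,
                t0_h,
                dt_h,
            )
        )
    return out
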