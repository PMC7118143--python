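"""Two-step pipeline orchestration: shape profiling, then path statistics.

Ties the stages together in the order a study runs them:

1. ``simulate`` — generate ground-truth cells for the two scenario groups
   (and optionally render image stacks);
2. ``track`` — trajectories from detected nuclei (rendered mode) or from
   the ground-truth positions (table mode), smoothed and differentiated;
3. ``segment`` — per-frame cell-body ellipse fits (rendered mode) or
   truth-derived shape tables;
4. ``angles`` — projected paths from first-half positions, the three
   angular statistics on latter-half frames, the bivariate density and
   its peak, the accordance rate;
5. ``compare`` — shape-metric t tests plus the two resampling tests.

Every stage writes plain CSV/JSON artifacts; a manifest records the
config hash, the seed and the SHA-256 of every file so a rerun with the
same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import cellbody, grouptests, pathstats, synthgen, tracking

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "run_pipeline",
    "exclusion_report",
    "tracks_frame",
    "shapes_from_truth",
    "angles_frame",
    "angle_records_for_group",
]

log = logging.getLogger("shapepath")

FLOAT_FMT = "%.6f"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Full configuration with the pipeline's standard constants as defaults."""

    out_dir: str = "shapepath_out"
    rng_seed: int = 0
    render: bool = False
    image_shape: tuple = (760, 1088)
    scenario_a: synthgen.SimScenario = field(default_factory=synthgen.hc_like)
    scenario_b: synthgen.SimScenario = field(default_factory=synthgen.reln_del_like)
    segmentation: cellbody.SegmentationConfig = field(default_factory=cellbody.SegmentationConfig)
    tracking: tracking.TrackingConfig = field(default_factory=tracking.TrackingConfig)
    first_half_h: tuple = (42.0, 47.75)
    latter_half_h: tuple = (48.0, 54.0)
    bandwidth_deg: float = 20.0
    accordance_half_width_deg: float = 15.0
    peak_trials: int = 10_000
    accordance_trials: int = 1000

    def validate(self):
        a0, a1 = self.first_half_h
        b0, b1 = self.latter_half_h
        if not (a0 < a1 <= b0 < b1):
            raise ValueError(
                f"analysis windows must be ordered and non-overlapping, got "
                f"{self.first_half_h} and {self.latter_half_h}"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (
            ("scenario_a", synthgen.SimScenario),
            ("scenario_b", synthgen.SimScenario),
            ("segmentation", cellbody.SegmentationConfig),
            ("tracking", tracking.TrackingConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        for key in ("image_shape", "first_half_h", "latter_half_h"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("out_dir", None)  # location is not part of the analysis identity
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def _derived_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def tracks_frame(trajectories) -> pd.DataFrame:
    rows = []
    for tr in trajectories:
        n = len(tr.frames)
        for k in range(n):
            vx, vy = (tr.movement_vec[k] if k < n - 1 else (np.nan, np.nan))
            rows.append(
                {
                    "cell_id": tr.cell_id,
                    "frame": int(tr.frames[k]),
                    "time_h": float(tr.times_h[k]),
                    "raw_x": tr.raw_xy[k, 0],
                    "raw_y": tr.raw_xy[k, 1],
                    "smooth_x": tr.smooth_xy[k, 0],
                    "smooth_y": tr.smooth_xy[k, 1],
                    "vx": vx,
                    "vy": vy,
                }
            )
    return pd.DataFrame(rows)


def shapes_from_truth(gt: pd.DataFrame) -> pd.DataFrame:
    df = gt.copy()
    out = pd.DataFrame(
        {
            "cell_id": df["cell_id"],
            "frame": df["frame"],
            "time_h": df["time_h"],
            "centroid_x": df["x"],
            "centroid_y": df["y"],
            "area_px": np.pi * df["major_px"] * df["minor_px"] / 4.0,
            "major_px": df["major_px"],
            "minor_px": df["minor_px"],
            "orientation_deg": df["orientation_deg"],
            "eccentricity": np.sqrt(1.0 - (df["minor_px"] / df["major_px"]) ** 2),
            "solidity": 1.0,
            "excluded": False,
            "reason": "",
        }
    )
    return out


def angle_records_for_group(
    trajectories,
    shapes: pd.DataFrame,
    first_half_h=(42.0, 47.75),
    latter_half_h=(48.0, 54.0),
) -> list:
    """Fit each cell's projected path and collect latter-half AngleRecords."""
    records = []
    shapes_by_cell = {cid: g for cid, g in shapes.groupby("cell_id")}
    for tr in trajectories:
        pts = tr.positions_in_window(first_half_h, smoothed=True)
        if len(pts) < 5:
            log.warning("cell %s: <5 first-half points, skipped", tr.cell_id)
            continue
        try:
            path = pathstats.fit_projected_path(
                pts, cell_id=tr.cell_id, fit_window_h=first_half_h
            )
        except pathstats.DegeneratePathError:
            log.warning("cell %s: degenerate path, skipped", tr.cell_id)
            continue
        g = shapes_by_cell.get(tr.cell_id)
        ori = {}
        if g is not None:
            for _, r in g.iterrows():
                ori[int(r["frame"])] = (
                    None if bool(r["excluded"]) else float(r["orientation_deg"])
                )
        records.extend(pathstats.compute_angles(tr, ori, path, latter_half_h))
    return records


def angles_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": r.cell_id,
                "frame": r.frame,
                "time_h": r.time_h,
                "rotation_deg": r.rotation_deg,
                "turning_deg": r.turning_deg,
                "accordance_deg": r.accordance_deg,
                "valid": r.valid,
            }
            for r in records
        ]
    )


def exclusion_report(shapes: pd.DataFrame, angles: pd.DataFrame | None = None) -> dict:
    """Counts and percentages of frames excluded, by reason.

    Shape-QC reasons come from the shapes table; stationary frames
    (zero movement vector while the shape was retained) come from the
    angles table when given.  Every excluded frame lands in exactly one
    bucket.
    """
    n_total = len(shapes)
    reasons = {}
    excl = shapes[shapes["excluded"].astype(bool)]
    for reason, grp in excl.groupby("reason"):
        reasons[reason or "unspecified"] = len(grp)
    if angles is not None and len(angles):
        retained = shapes[~shapes["excluded"].astype(bool)][["cell_id", "frame"]]
        keys = set(map(tuple, retained.to_numpy()))
        invalid = angles[~angles["valid"].astype(bool)]
        n_zero = sum(
            1 for _, r in invalid.iterrows() if (r["cell_id"], r["frame"]) in keys
        )
        if n_zero:
            reasons["zero-movement"] = n_zero
    n_excluded = sum(reasons.values())
    pct = 100.0 * n_excluded / n_total if n_total else 0.0
    return {
        "n_frames": n_total,
        "n_excluded": n_excluded,
        "by_reason": dict(sorted(reasons.items())),
        "formatted": f"{n_excluded}/{n_total} ({pct:.1f}%)",
    }


def _write_csv(df: pd.DataFrame, path):
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    return path


def _write_json(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
    return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and return the manifest (also written to disk).

    Rerunning with the same config and seed reproduces byte-identical
    outputs; any stage failure raises :class:`PipelineError` naming the
    stage.
    """
    cfg = config
    cfg.validate()
    os.makedirs(cfg.out_dir, exist_ok=True)
    seeds = _derived_seeds(cfg.rng_seed, 8)
    manifest = {"config_hash": cfg.config_hash(), "rng_seed": cfg.rng_seed, "stages": {}}
    groups = {}

    # --- simulate -----------------------------------------------------
    stage_files = []
    try:
        for i, (label, scen) in enumerate(
            (("A", cfg.scenario_a), ("B", cfg.scenario_b))
        ):
            scen = dataclasses.replace(scen, rng_seed=seeds[i])
            cells = synthgen.simulate_tracks(scen)
            gt = synthgen.ground_truth_frame(cells, scen.t0_h, scen.dt_h)
            path = os.path.join(cfg.out_dir, f"group{label}_ground_truth.csv")
            stage_files.append(_write_csv(gt, path))
            groups[label] = {"scenario": scen, "cells": cells, "gt": gt}
            if cfg.render:
                pairs = synthgen.render_frames(
                    cells, cfg.image_shape, rng_seed=seeds[2 + i],
                    t0_h=scen.t0_h, dt_h=scen.dt_h,
                )
                p1, p2 = synthgen.write_frame_stacks(
                    pairs, cfg.out_dir, prefix=f"group{label}_"
                )
                stage_files.extend([p1, p2])
                groups[label]["pairs"] = pairs
    except Exception as e:  # pragma: no cover - error path
        if isinstance(e, PipelineError):
            raise
        raise PipelineError("simulate", str(e)) from e
    manifest["stages"]["simulate"] = stage_files
    log.info("simulate: %d groups", len(groups))

    # --- track --------------------------------------------------------
    stage_files = []
    try:
        for label, g in groups.items():
            scen = g["scenario"]
            if cfg.render:
                dets = [
                    tracking.detect_nuclei(
                        p.gfp_image,
                        cfg.tracking.gfp_threshold_method,
                        cfg.tracking.min_blob_px,
                    )
                    for p in g["pairs"]
                ]
                trajs = tracking.link_tracks(
                    dets,
                    cfg.tracking.max_link_px,
                    cfg.tracking.min_track_frames,
                    cfg.tracking.smooth_window,
                    scen.t0_h,
                    scen.dt_h,
                )
            else:
                trajs = tracking.trajectories_from_positions(
                    g["gt"], cfg.tracking.smooth_window, t0_h=scen.t0_h, dt_h=scen.dt_h
                )
            if not trajs:
                raise PipelineError("track", f"group {label}: no tracks")
            g["trajectories"] = trajs
            path = os.path.join(cfg.out_dir, f"group{label}_tracks.csv")
            stage_files.append(_write_csv(tracks_frame(trajs), path))
    except Exception as e:
        if isinstance(e, PipelineError):
            raise
        raise PipelineError("track", str(e)) from e
    manifest["stages"]["track"] = stage_files

    # --- segment ------------------------------------------------------
    stage_files = []
    try:
        for label, g in groups.items():
            scen = g["scenario"]
            if cfg.render:
                pos = tracks_frame(g["trajectories"])[
                    ["cell_id", "frame", "raw_x", "raw_y"]
                ].rename(columns={"raw_x": "x", "raw_y": "y"})
                phase = [p.phase_image for p in g["pairs"]]
                shapes = cellbody.segment_positions(
                    phase, pos, cfg.segmentation, t0_h=scen.t0_h, dt_h=scen.dt_h
                )
            else:
                shapes = shapes_from_truth(g["gt"])
            g["shapes"] = shapes
            path = os.path.join(cfg.out_dir, f"group{label}_shapes.csv")
            stage_files.append(_write_csv(shapes, path))
    except Exception as e:
        if isinstance(e, PipelineError):
            raise
        raise PipelineError("segment", str(e)) from e
    manifest["stages"]["segment"] = stage_files

    # --- angles -------------------------------------------------------
    stage_files = []
    try:
        for label, g in groups.items():
            recs = angle_records_for_group(
                g["trajectories"], g["shapes"], cfg.first_half_h, cfg.latter_half_h
            )
            valid = [r for r in recs if r.valid]
            if not valid:
                raise PipelineError(
                    "angles", f"group {label}: no valid angle records"
                )
            g["records"] = recs
            adf = angles_frame(recs)
            stage_files.append(
                _write_csv(adf, os.path.join(cfg.out_dir, f"group{label}_angles.csv"))
            )
            surf = pathstats.bivariate_density(recs, cfg.bandwidth_deg)
            g["surface"] = surf
            dens = pd.DataFrame(
                surf.density, index=surf.grid_rotation, columns=surf.grid_turning
            )
            stage_files.append(
                _write_csv(
                    dens.reset_index().rename(columns={"index": "rotation_deg"}),
                    os.path.join(cfg.out_dir, f"group{label}_density.csv"),
                )
            )
            summary = {
                "group": label,
                "n_records": len(valid),
                "peak_density_per_deg2": surf.peak(),
                "accordance_rate": pathstats.accordance_rate(
                    recs, cfg.accordance_half_width_deg
                ),
                "exclusions": exclusion_report(g["shapes"], adf),
            }
            g["summary"] = summary
            stage_files.append(
                _write_json(
                    summary, os.path.join(cfg.out_dir, f"group{label}_summary.json")
                )
            )
    except Exception as e:
        if isinstance(e, PipelineError):
            raise
        raise PipelineError("angles", str(e)) from e
    manifest["stages"]["angles"] = stage_files

    # --- compare ------------------------------------------------------
    stage_files = []
    try:
        ga, gb = groups["A"], groups["B"]
        metrics = grouptests.compare_shape_metrics(
            ga["shapes"], gb["shapes"],
            labels=(ga["scenario"].name, gb["scenario"].name),
        )
        ra = [r for r in ga["records"] if r.valid]
        rb = [r for r in gb["records"] if r.valid]
        peak_test = grouptests.peak_density_resample_test(
            [r.rotation_deg for r in ra],
            [r.turning_deg for r in ra],
            gb["surface"].peak(),
            n_trials=cfg.peak_trials,
            resample_size=len(rb),
            rng_seed=seeds[4],
            bandwidth_deg=cfg.bandwidth_deg,
        )
        acc_fwd = grouptests.accordance_resample_test(
            [r.accordance_deg for r in ra],
            gb["summary"]["accordance_rate"],
            n_trials=cfg.accordance_trials,
            resample_size=len(rb),
            rng_seed=seeds[5],
            half_width_deg=cfg.accordance_half_width_deg,
        )
        acc_rev = grouptests.accordance_resample_test(
            [r.accordance_deg for r in rb],
            ga["summary"]["accordance_rate"],
            n_trials=cfg.accordance_trials,
            resample_size=len(ra),
            rng_seed=seeds[6],
            half_width_deg=cfg.accordance_half_width_deg,
        )
        report = {
            "groups": {label: g["summary"] for label, g in groups.items()},
            "shape_metric_tests": [asdict(m) for m in metrics],
            "peak_density_resample_test": asdict(peak_test),
            "accordance_resample_test_forward": asdict(acc_fwd),
            "accordance_resample_test_reverse": asdict(acc_rev),
        }
        stage_files.append(
            _write_json(report, os.path.join(cfg.out_dir, "compare_report.json"))
        )
    except Exception as e:
        if isinstance(e, PipelineError):
            raise
        raise PipelineError("compare", str(e)) from e
    manifest["stages"]["compare"] = stage_files

    manifest["files"] = {
        os.path.basename(p): _sha256(p)
        for files in manifest["stages"].values()
        for p in files
    }
    _write_json(manifest, os.path.join(cfg.out_dir, "manifest.json"))
    return manifest
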