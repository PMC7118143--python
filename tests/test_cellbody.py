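"""Segmentation-chain and ellipse-fitting contracts."""

import os

import numpy as np
import pytest
from scipy import ndimage

from shapepath import cellbody as cb
from shapepath import synthgen as sg
from shapepath.pathstats import fold_axis_deg

from conftest import single_cell

FIXTURES = os.path.join(os.path.dirname(__file__), "fixtures")


def brute_force_ellipse(mask):
    """Independent moments oracle: raw sums over pixel coordinates and an
    explicit symmetric eigendecomposition, no shared code with the package."""
    ys, xs = np.nonzero(np.asarray(mask, bool))
    cx, cy = xs.mean(), ys.mean()
    u = xs - cx
    v = -(ys - cy)
    C = np.array(
        [
            [np.sum(u * u), np.sum(u * v)],
            [np.sum(u * v), np.sum(v * v)],
        ]
    ) / xs.size
    w, V = np.linalg.eigh(C)  # ascending
    major = 4.0 * np.sqrt(w[1])
    minor = 4.0 * np.sqrt(max(w[0], 0.0))
    ang = np.degrees(np.arctan2(V[1, 1], V[0, 1]))
    return cx, cy, major, minor, (ang + 90.0) % 180.0 - 90.0


def raster_ellipse(major, minor, orientation_deg, shape=(64, 64), center=(32.0, 32.0)):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dx = xx - center[0]
    dy = -(yy - center[1])
    th = np.radians(orientation_deg)
    u = dx * np.cos(th) + dy * np.sin(th)
    v = -dx * np.sin(th) + dy * np.cos(th)
    return (u / (major / 2)) ** 2 + (v / (minor / 2)) ** 2 <= 1.0


class TestCrop:
    def test_centered_window_arithmetic(self):
        frame = np.zeros((760, 1088), dtype=np.uint8)
        crop, (x0, y0) = cb.crop_around_nucleus(frame, (544, 380), 244)
        assert crop.shape == (244, 244)
        assert (x0, y0) == (422, 258)
        assert x0 + 243 == 665  # spans columns 422..665 inclusive

    def test_clamped_at_border_with_offset(self):
        frame = np.zeros((300, 300), dtype=np.uint8)
        crop, (x0, y0) = cb.crop_around_nucleus(frame, (10, 10), 244)
        assert (x0, y0) == (0, 0)
        assert crop.shape == (244, 244)

    def test_oversized_crop_and_outside_nucleus_error(self):
        frame = np.zeros((100, 100), dtype=np.uint8)
        with pytest.raises(ValueError):
            cb.crop_around_nucleus(frame, (50, 50), 244)
        with pytest.raises(ValueError):
            cb.crop_around_nucleus(np.zeros((300, 300)), (400, 50), 244)


class TestDetectEdges:
    def test_constant_image_empty_mask(self):
        assert not cb.detect_edges(np.full((32, 32), 77, dtype=np.uint8)).any()

    def test_vertical_step_marks_step_columns(self):
        img = np.zeros((32, 32))
        img[:, 16:] = 200.0
        mask = cb.detect_edges(img)
        cols = np.unique(np.nonzero(mask)[1])
        assert set(cols) <= {15, 16}
        assert mask.sum() > 0

    def test_ring_around_rendered_ellipse_boundary(self):
        # >= 90% of oracle boundary pixels within 2 px of the edge mask
        cell = single_cell(major=14.0, minor=9.0, orientation=40.0)
        pair = sg.render_frames([cell], (48, 48), noise_sd=0.0, rng_seed=0)[0]
        mask = cb.detect_edges(pair.phase_image)
        oracle = sg.ellipse_mask((48, 48), cell, 0)
        boundary = oracle & ~ndimage.binary_erosion(oracle)
        dist_to_edge = ndimage.distance_transform_edt(~mask)
        frac = np.mean(dist_to_edge[boundary] <= 2.0)
        assert frac >= 0.9


class TestCloseObject:
    def test_thin_ring_closes_to_filled_disk(self):
        yy, xx = np.mgrid[0:32, 0:32]
        r = np.hypot(xx - 16, yy - 16)
        ring = (r >= 7.5) & (r <= 8.5)
        filled = cb.close_object(ring, 2)
        # pixel-count oracle: between disks of radius 8 and 9
        assert (r <= 8.0).sum() <= filled.sum() <= (r <= 9.0).sum() + 8
        assert filled[16, 16]

    def test_empty_stays_empty(self):
        assert not cb.close_object(np.zeros((16, 16), bool), 2).any()

    def test_two_rings_stay_two_objects(self):
        yy, xx = np.mgrid[0:40, 0:80]
        ring1 = np.abs(np.hypot(xx - 20, yy - 20) - 8) <= 0.6
        ring2 = np.abs(np.hypot(xx - 60, yy - 20) - 8) <= 0.6
        _, n = ndimage.label(cb.close_object(ring1 | ring2, 2))
        assert n == 2


class TestSelectCellBody:
    def _two_objects(self):
        mask = np.zeros((40, 40), bool)
        mask[5:10, 5:10] = True     # small, 25 px
        mask[20:35, 20:35] = True   # large, 225 px
        return mask

    def test_nucleus_containment_beats_size(self):
        sel = cb.select_cell_body(self._two_objects(), (7, 7), min_area_px=10)
        assert sel.sum() == 25

    def test_nearest_within_gate_when_outside(self):
        mask = np.zeros((40, 40), bool)
        mask[10:20, 10:20] = True
        sel = cb.select_cell_body(mask, (25, 15), min_area_px=10, nucleus_gate_px=10)
        assert sel is not None and sel.sum() == 100
        assert cb.select_cell_body(mask, (35, 15), min_area_px=10, nucleus_gate_px=10) is None

    def test_too_small_object_rejected(self):
        mask = np.zeros((20, 20), bool)
        mask[5:7, 5:7] = True  # 4 px
        assert cb.select_cell_body(mask, (5, 5), min_area_px=10) is None


class TestFitEllipse:
    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = raster_ellipse(
            rng.uniform(10, 24), rng.uniform(6, 12), rng.uniform(-90, 90)
        )
        fit = cb.fit_ellipse(mask)
        cx, cy, major, minor, ang = brute_force_ellipse(mask)
        assert fit.centroid_x == pytest.approx(cx, abs=1e-9)
        assert fit.centroid_y == pytest.approx(cy, abs=1e-9)
        assert fit.major_px == pytest.approx(major, rel=1e-6)
        assert fit.minor_px == pytest.approx(minor, rel=1e-6)
        if fit.major_px / max(fit.minor_px, 1e-9) > 1.05:
            assert float(fold_axis_deg(fit.orientation_deg - ang)) == pytest.approx(0.0, abs=1e-6)

    def test_matches_skimage_regionprops_convention(self):
        from skimage.measure import regionprops

        mask = raster_ellipse(22, 10, 30.0)
        fit = cb.fit_ellipse(mask)
        rp = regionprops(mask.astype(int))[0]
        assert fit.major_px == pytest.approx(rp.axis_major_length, rel=1e-9)
        assert fit.minor_px == pytest.approx(rp.axis_minor_length, rel=1e-9)
        assert fit.eccentricity == pytest.approx(rp.eccentricity, rel=1e-9)
        # skimage measures orientation from the row axis; +90 deg maps it to
        # the math convention used here
        assert fit.orientation_deg == pytest.approx(
            float(fold_axis_deg(np.degrees(rp.orientation) + 90.0)), abs=1e-6
        )

    def test_disk_recovery(self):
        yy, xx = np.mgrid[0:32, 0:32]
        mask = np.hypot(xx - 16, yy - 16) <= 10.0
        fit = cb.fit_ellipse(mask)
        assert fit.major_px == pytest.approx(20.0, rel=0.05)
        assert fit.minor_px == pytest.approx(20.0, rel=0.05)
        assert fit.eccentricity < 0.1

    def test_axis_aligned_ellipse_recovery(self):
        mask = raster_ellipse(24, 12, 0.0)
        fit = cb.fit_ellipse(mask)
        assert fit.major_px == pytest.approx(24.0, rel=0.03)
        assert fit.minor_px == pytest.approx(12.0, rel=0.03)
        assert abs(fit.orientation_deg) < 3.0

    def test_single_row_is_degenerate(self):
        mask = np.zeros((10, 10), bool)
        mask[4, 2:7] = True
        fit = cb.fit_ellipse(mask)
        assert fit.excluded and fit.reason == "degenerate"
        assert fit.minor_px == 0.0

    def test_eccentricity_consistency_invariant(self):
        mask = raster_ellipse(18, 9, -50.0)
        fit = cb.fit_ellipse(mask)
        assert fit.eccentricity == pytest.approx(
            cb.eccentricity_of(fit.minor_px, fit.major_px), abs=1e-9
        )


class TestEccentricity:
    @pytest.mark.parametrize(
        "minor,major,expected",
        [(6.0, 10.0, 0.8), (10.0, 10.0, 0.0), (7.22, 11.2, 0.7645)],
    )
    def test_values(self, minor, major, expected):
        assert cb.eccentricity_of(minor, major) == pytest.approx(expected, abs=5e-4)

    def test_minor_exceeding_major_rejected(self):
        with pytest.raises(ValueError):
            cb.eccentricity_of(11.0, 10.0)


class TestQcFilter:
    def test_crescent_excluded_by_solidity(self):
        yy, xx = np.mgrid[0:40, 0:40]
        disk_big = np.hypot(xx - 20, yy - 20) <= 12
        disk_cut = np.hypot(xx - 26, yy - 20) <= 10
        crescent = disk_big & ~disk_cut
        fit = cb.fit_ellipse(crescent)
        assert fit.solidity < 0.7
        assert cb.qc_filter(fit, 0.7).excluded
        assert cb.qc_filter(fit, 0.7).reason == "low-solidity"

    def test_convex_object_retained(self):
        fit = cb.fit_ellipse(raster_ellipse(20, 12, 10.0))
        assert fit.solidity > 0.9
        assert not cb.qc_filter(fit, 0.7).excluded

    def test_exactly_at_threshold_retained(self):
        fit = cb.EllipseFit(0, 0, 0, 100, 10, 5, 0, 0.86, solidity=0.7)
        assert not cb.qc_filter(fit, 0.7).excluded


class TestRecoveryOnRenders:
    def test_area_and_orientation_recovered(self, hc_rendered):
        cells, pairs = hc_rendered
        cfg = cb.SegmentationConfig()
        area_err, ori_err = [], []
        for f in (0, 16, 32, 47):
            for c in cells:
                fit = cb.profile_frame(pairs[f].phase_image, tuple(c.xy[f]), cfg, f)
                if fit.excluded:
                    continue
                true_area = np.pi * c.major_px[f] * c.minor_px[f] / 4.0
                area_err.append((fit.area_px - true_area) / true_area)
                if c.eccentricity > 0.3:
                    ori_err.append(
                        abs(float(fold_axis_deg(fit.orientation_deg - c.orientation_deg[f])))
                    )
        assert len(area_err) >= 40
        assert abs(np.mean(area_err)) <= 0.05
        assert np.mean(ori_err) <= 5.0

    def test_matches_reference_annotations(self):
        # fixed synthetic fields with stored reference annotations (traced
        # from the rendered contrast; see fixtures/) -- automated areas agree
        # within 10%, mirroring a manual-vs-automated validation
        cases = {
            "a": (12.0, 8.0, 30.0),
            "b": (14.0, 6.0, -60.0),
            "c": (10.0, 10.0, 0.0),
        }
        cfg = cb.SegmentationConfig(crop_size=48)
        for name, (major, minor, ori) in cases.items():
            cell = single_cell(major=major, minor=minor, orientation=ori)
            pair = sg.render_frames([cell], (48, 48), noise_sd=0.0, rng_seed=0)[0]
            with open(os.path.join(FIXTURES, f"annotated_cell_{name}.txt")) as fh:
                annot = np.array(
                    [[ch == "#" for ch in line.rstrip("\n")] for line in fh]
                )
            fit = cb.profile_frame(pair.phase_image, (24.0, 24.0), cfg)
            assert not fit.excluded
            assert abs(fit.area_px - annot.sum()) / annot.sum() <= 0.10

    def test_empty_frame_flagged_no_object(self):
        frame = np.full((64, 64), 128, dtype=np.uint8)
        fit = cb.profile_frame(frame, (32.0, 32.0), cb.SegmentationConfig(crop_size=48))
        assert fit.excluded and fit.reason == "no-object"
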