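"""Projected-path, angle-operation and density-surface contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shapepath import pathstats as ps
from shapepath import synthgen as sg
from shapepath import tracking as tk
from shapepath import pipeline as pl


def make_path(heading_deg, cell_id=None):
    rad = np.radians(heading_deg)
    return ps.ProjectedPath(
        cell_id=cell_id,
        direction=np.array([np.cos(rad), -np.sin(rad)]),
        anchor=np.zeros(2),
        n_points_used=5,
        robust_scale=0.0,
    )


class TestFitProjectedPath:
    def test_exact_line_recovered(self):
        x = np.arange(10.0)
        pts = np.column_stack([x, 2.0 * x + 1.0])
        path = ps.fit_projected_path(pts)
        np.testing.assert_allclose(path.direction, [1, 2] / np.sqrt(5), atol=1e-9)

    def test_gross_outlier_resisted_within_one_degree(self):
        # oracle: ordinary least squares on the clean subset
        x = np.arange(12.0)
        pts = np.column_stack([x, 2.0 * x + 1.0])
        rng = np.random.default_rng(1)
        pts += rng.normal(0, 0.05, pts.shape)
        clean_slope = np.polyfit(pts[:, 0], pts[:, 1], 1)[0]
        clean_heading = np.degrees(np.arctan2(-clean_slope, 1))
        dirty = np.vstack([pts, [[6.0, 60.0]]])
        path = ps.fit_projected_path(dirty)
        assert abs(float(ps.wrap_signed_deg(path.heading - clean_heading))) < 1.0

    def test_vertical_motion_handled(self):
        pts = np.column_stack([np.full(8, 3.0), np.arange(8.0)])
        path = ps.fit_projected_path(pts)
        np.testing.assert_allclose(np.abs(path.direction), [0, 1], atol=1e-9)
        # sign follows net displacement (downward in image coords)
        assert path.direction[1] > 0

    def test_direction_sign_follows_net_displacement(self):
        x = np.arange(10.0)[::-1]  # moving in -x
        pts = np.column_stack([x, 0.5 * x])
        path = ps.fit_projected_path(pts)
        assert path.direction[0] < 0

    def test_degenerate_and_short_inputs_rejected(self):
        with pytest.raises(ps.DegeneratePathError):
            ps.fit_projected_path(np.tile([1.0, 2.0], (8, 1)))
        with pytest.raises(ValueError):
            ps.fit_projected_path(np.zeros((4, 2)))

    def test_cross_checks_against_statsmodels_rlm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        x = np.linspace(0, 20, 24)
        y = 1.5 + 0.7 * x + rng.normal(0, 0.4, x.size)
        y[3] += 25.0  # gross outlier
        path = ps.fit_projected_path(np.column_stack([x, y]))
        rlm = sm.RLM(
            y, sm.add_constant(x), M=sm.robust.norms.TukeyBiweight(4.685)
        ).fit()
        slope = rlm.params[1]
        ref_heading = np.degrees(np.arctan2(-slope, 1.0))
        assert abs(float(ps.wrap_signed_deg(path.heading - ref_heading))) < 0.5


class TestAngleOperations:
    @pytest.mark.parametrize(
        "axis,path_heading,expected",
        [(30.0, 30.0, 0.0), (100.0, 0.0, -80.0), (-90.0, 85.0, 5.0)],
    )
    def test_axis_rotation(self, axis, path_heading, expected):
        assert float(ps.axis_rotation(axis, make_path(path_heading))) == pytest.approx(
            expected, abs=1e-9
        )

    @pytest.mark.parametrize(
        "vec,path_heading,expected",
        [
            ((1.0, 0.0), 0.0, 0.0),
            ((-1.0, 0.0), 0.0, 180.0),
            ((1.0, -1.0), 0.0, 45.0),  # image dy=-1 is upward
        ],
    )
    def test_turning_angle(self, vec, path_heading, expected):
        assert ps.turning_angle(vec, make_path(path_heading)) == pytest.approx(
            expected, abs=1e-9
        )

    @pytest.mark.parametrize(
        "heading,axis,expected_abs",
        [(10.0, 10.0, 0.0), (0.0, 90.0, 90.0), (170.0, 0.0, 10.0)],
    )
    def test_accordance_angle(self, heading, axis, expected_abs):
        rad = np.radians(heading)
        vec = (np.cos(rad), -np.sin(rad))
        assert abs(ps.accordance_angle(vec, axis)) == pytest.approx(
            expected_abs, abs=1e-9
        )

    def test_zero_vector_raises(self):
        with pytest.raises(ValueError):
            ps.turning_angle((0.0, 0.0), make_path(0.0))
        with pytest.raises(ValueError):
            ps.accordance_angle((0.0, 0.0), 30.0)

    def test_range_contracts_on_many_random_inputs(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-1e4, 1e4, 1_000_000)
        folded = ps.fold_axis_deg(x)
        wrapped = ps.wrap_signed_deg(x)
        assert np.all((folded >= -90.0) & (folded < 90.0))
        assert np.all((wrapped > -180.0) & (wrapped <= 180.0))
        # folding preserves the axis (mod 180), wrapping the angle (mod 360)
        mf = (folded - x) % 180.0
        mw = (wrapped - x) % 360.0
        assert np.all(np.minimum(mf, 180.0 - mf) < 1e-6)
        assert np.all(np.minimum(mw, 360.0 - mw) < 1e-6)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(-1e6, 1e6))
    def test_fold_and_wrap_match_slow_reference(self, x):
        f = float(ps.fold_axis_deg(x))
        w = float(ps.wrap_signed_deg(x))
        ref_f = x
        while ref_f >= 90.0:
            ref_f -= 180.0
        while ref_f < -90.0:
            ref_f += 180.0
        ref_w = x
        while ref_w > 180.0:
            ref_w -= 360.0
        while ref_w <= -180.0:
            ref_w += 360.0
        assert f == pytest.approx(ref_f, abs=1e-6)
        assert w == pytest.approx(ref_w, abs=1e-6)


class TestDensitySurface:
    def test_delta_data_peak_matches_kernel_height(self):
        surf = ps.kde_surface(np.zeros(50), np.zeros(50), 20.0)
        expected = 1.0 / (2.0 * np.pi * 400.0)  # 3.9789e-4 per deg^2
        assert surf.peak() == pytest.approx(expected, rel=0.02)
        assert surf.integral() == pytest.approx(1.0, abs=0.01)

    def test_gaussian_pairs_match_convolution_closed_form(self):
        rng = np.random.default_rng(12)
        z = rng.normal(0.0, 37.0, size=(100_000, 2))
        surf = ps.kde_surface(z[:, 0], z[:, 1], 20.0)
        expected = 1.0 / (2.0 * np.pi * (37.0**2 + 400.0))
        assert surf.peak() == pytest.approx(expected, rel=0.05)

    def test_sign_symmetric_data_gives_symmetric_density(self):
        rot = np.array([10.0, -10.0, 25.0, -25.0, 0.0, 40.0, -40.0, 5.0, -5.0, 0.0])
        turn = np.array([30.0, -30.0, 0.0, 0.0, 15.0, -15.0, 15.0, -15.0, 60.0, -60.0])
        rot = np.concatenate([rot, -rot])
        turn = np.concatenate([turn, -turn])
        surf = ps.kde_surface(rot, turn, 20.0)
        np.testing.assert_allclose(surf.density, surf.density[::-1, ::-1], atol=1e-12)

    def test_integral_is_one_for_varied_inputs(self):
        rng = np.random.default_rng(3)
        for spread in (5.0, 30.0, 80.0):
            surf = ps.kde_surface(
                rng.normal(0, spread, 500), rng.normal(0, spread * 1.5, 500), 20.0
            )
            assert surf.integral() == pytest.approx(1.0, abs=0.01)

    def test_peak_invariant_to_order_and_duplication(self):
        rng = np.random.default_rng(8)
        rot, turn = rng.normal(0, 30, 200), rng.normal(0, 50, 200)
        p1 = ps.kde_surface(rot, turn).peak()
        perm = rng.permutation(200)
        p2 = ps.kde_surface(rot[perm], turn[perm]).peak()
        p3 = ps.kde_surface(np.tile(rot, 3), np.tile(turn, 3)).peak()
        assert p1 == pytest.approx(p2, rel=1e-12)
        assert p1 == pytest.approx(p3, rel=1e-12)

    def test_too_few_valid_records_rejected(self):
        recs = [
            ps.AngleRecord(0, f, 48.0, 0.0, 0.0, 0.0, valid=(f < 5)) for f in range(12)
        ]
        with pytest.raises(ValueError):
            ps.bivariate_density(recs)


class TestAccordanceRate:
    def test_all_zero_angles(self):
        assert ps.accordance_rate(np.zeros(10)) == 1.0

    def test_uniform_angles_measure_ratio(self):
        ang = np.linspace(-89.99, 89.99, 20_000)
        assert ps.accordance_rate(ang) == pytest.approx(30.0 / 180.0, abs=1e-3)

    def test_calibrated_sample_recovers_target(self):
        sigma = sg.calibrate_coupling(0.396, 15.0)
        rng = np.random.default_rng(6)
        ang = ps.fold_axis_deg(rng.normal(0.0, sigma, 10_000))
        assert ps.accordance_rate(ang) == pytest.approx(0.396, abs=0.015)

    def test_boundary_is_strict(self):
        ang = np.array([15.0, -15.0, 14.999, -14.999])
        assert ps.accordance_rate(ang) == 0.5


class TestAnalysisWindows:
    def test_first_half_frames_never_leak_into_statistics(self, hc_cells):
        _, cells = hc_cells
        gt = sg.ground_truth_frame(cells)
        trajs = tk.trajectories_from_positions(gt)
        shapes = pl.shapes_from_truth(gt)
        recs = pl.angle_records_for_group(
            trajs, shapes, first_half_h=(42.0, 47.75), latter_half_h=(48.0, 54.0)
        )
        times = np.array([r.time_h for r in recs])
        assert times.min() >= 48.0 and times.max() <= 54.0
        # the fit window itself is recorded on the path object
        path = ps.fit_projected_path(
            trajs[0].positions_in_window((42.0, 47.75)), fit_window_h=(42.0, 47.75)
        )
        assert path.fit_window_h == (42.0, 47.75)
        assert path.n_points_used == 24  # 42.0 .. 47.75 at 0.25 h steps
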