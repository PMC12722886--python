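"""Chest-wall mesh volumetry against analytic and convex-hull oracles."""

import numpy as np
import pytest
from scipy.spatial import ConvexHull
from scipy.spatial.transform import Rotation

from respmech.chestwall import (
    GridError,
    build_grid,
    canonical_layout,
    frame_volume,
    volume_series,
)
from respmech.mocap_io import MarkerTrajectorySet

from conftest import cylinder_grid, cylinder_markers


class TestBuildGrid:
    def test_canonical_spec_echo(self, default_grid):
        assert (default_grid.rows, default_grid.cols) == (4, 8)
        assert default_grid.band_rows() == [(0, 1), (1, 2), (2, 3)]

    def test_missing_cell_named(self):
        layout = canonical_layout()
        del layout["cells"]["CW_2_5"]
        labels = list(layout["cells"])
        with pytest.raises(GridError, match=r"row 2, col 5"):
            build_grid(labels, layout)

    def test_duplicate_cell_rejected(self):
        layout = canonical_layout()
        layout["cells"]["CW_0_1"] = [0, 0]
        with pytest.raises(GridError, match="cell"):
            build_grid(list(layout["cells"]), layout)

    def test_label_order_irrelevant(self):
        layout = canonical_layout()
        labels = list(layout["cells"])
        rng = np.random.default_rng(0)
        shuffled = list(rng.permutation(labels))
        assert build_grid(labels, layout) == build_grid(shuffled, layout)


class TestFrameVolume:
    def test_unit_cube(self):
        """8 markers at unit-cube corners (2x4 grid, mm) enclose 1e-6 L."""
        labels, grid = cylinder_grid(2, 4)
        # top ring then bottom ring, counterclockwise seen from above
        pts = np.array(
            [
                [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
                [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
            ],
            dtype=float,
        )
        total, _ = frame_volume(pts, grid)
        assert total == pytest.approx(1e-6, rel=1e-12)

    def test_octagonal_prism_matches_polygon_area_oracle(self):
        """A cylinder sampled at 8 columns meshes to the inscribed-octagon
        prism: V = h * 2 sqrt(2) r^2."""
        r, h = 150.0, 600.0
        labels, grid = cylinder_grid(4, 8)
        total, comps = frame_volume(cylinder_markers(r, h, 4, 8), grid)
        analytic = h * 2.0 * np.sqrt(2.0) * r * r * 1e-6
        assert total == pytest.approx(analytic, rel=1e-9)
        assert total == pytest.approx(sum(comps.values()), abs=1e-12)

    @pytest.mark.parametrize("cols,tol", [(8, 0.11), (16, 0.026), (32, 0.0065), (64, 0.0017)])
    def test_grid_refinement_approaches_true_cylinder(self, cols, tol):
        r, h = 150.0, 600.0
        labels, grid = cylinder_grid(4, cols)
        total, _ = frame_volume(cylinder_markers(r, h, 4, cols), grid)
        err = abs(total - np.pi * r * r * h * 1e-6) / (np.pi * r * r * h * 1e-6)
        assert err < tol

    def test_refinement_error_is_monotone(self):
        r, h = 150.0, 600.0
        errors = []
        for cols in (8, 16, 32, 64):
            labels, grid = cylinder_grid(4, cols)
            total, _ = frame_volume(cylinder_markers(r, h, 4, cols), grid)
            errors.append(abs(total - np.pi * r * r * h * 1e-6))
        assert all(a > b for a, b in zip(errors, errors[1:]))

    def test_random_convex_rings_match_convex_hull(self):
        """Rings sampled on random convex bodies: the band mesh volume must
        equal the hull volume (hull of a convex point set = the mesh)."""
        rng = np.random.default_rng(42)
        labels, grid = cylinder_grid(4, 8)
        for _ in range(5):
            # random elliptic prism: every mesh facet is planar, so the
            # triangulated surface and the hull enclose the same solid
            pts = cylinder_markers(100.0 + 50.0 * rng.random(), 400.0, 4, 8)
            pts[:, 0] *= 0.8 + 0.4 * rng.random()
            pts[:, 1] *= 0.8 + 0.4 * rng.random()
            total, _ = frame_volume(pts, grid)
            hull = ConvexHull(pts).volume * 1e-6
            assert total == pytest.approx(hull, rel=1e-6)

    def test_convex_barrel_close_to_hull(self):
        """With a concave-down radius profile the solid is convex; mesh and
        hull differ only by the non-planar-quad diagonal choice (< 0.2%)."""
        labels, grid = cylinder_grid(4, 8)
        pts = cylinder_markers(120.0, 450.0, 4, 8).reshape(4, 8, 3)
        barrel = 1.0 + 0.25 * np.sin(np.pi * np.linspace(0.1, 0.9, 4))
        pts[..., :2] *= barrel[:, None, None]
        total, _ = frame_volume(pts.reshape(32, 3), grid)
        hull = ConvexHull(pts.reshape(32, 3)).volume * 1e-6
        assert total == pytest.approx(hull, rel=2e-3)
        assert total <= hull + 1e-12  # mesh is inscribed in its hull

    def test_rigid_motion_invariance(self, default_grid):
        pts = cylinder_markers(140.0, 450.0, 4, 8)
        total0, comps0 = frame_volume(pts, default_grid)
        rot = Rotation.from_euler("xyz", [20, -35, 60], degrees=True).as_matrix()
        moved = pts @ rot.T + np.array([1234.5, -987.6, 555.5])
        total1, comps1 = frame_volume(moved, default_grid)
        assert total1 == pytest.approx(total0, rel=1e-9)
        for k in comps0:
            assert comps1[k] == pytest.approx(comps0[k], rel=1e-9)

    def test_degenerate_mesh_flags_not_raises(self, default_grid):
        pts = cylinder_markers(140.0, 450.0, 4, 8)
        pts[3], pts[5] = pts[5].copy(), pts[3].copy()  # self-intersecting ring
        total, comps = frame_volume(pts, default_grid)
        assert np.isnan(total) or total > 0  # never raises; NaN when detected
        missing = pts.copy()
        missing[0] = np.nan
        total, _ = frame_volume(missing, default_grid)
        assert np.isnan(total)


class TestVolumeSeries:
    def test_static_trunk_constant_series(self, default_grid):
        pts = cylinder_markers(140.0, 450.0, 4, 8)
        pos = np.repeat(pts[None], 50, axis=0)
        m = MarkerTrajectorySet(default_grid.labels, pos, 100.0)
        series = volume_series(m, default_grid)
        assert series.total.std() < 1e-9
        assert series.valid_mask.all()

    def test_compartments_sum_to_total_every_valid_frame(self, noisy_trial, default_grid):
        m = noisy_trial.bundle.markers.subset(default_grid.labels)
        series = volume_series(m, default_grid)
        stacked = sum(series.compartments.values())
        np.testing.assert_allclose(
            stacked[series.valid_mask], series.total[series.valid_mask], atol=1e-9
        )

    def test_breathing_amplitude_matches_generator(self, quiet_trial, default_grid):
        """Mesh peak-trough amplitude reproduces the configured tidal volume."""
        series = volume_series(quiet_trial.bundle.markers, default_grid)
        analytic = quiet_trial.truth.analytic_volume
        np.testing.assert_allclose(series.total, analytic.total, rtol=1e-9)
        amplitude = series.total.max() - series.total.min()
        assert amplitude == pytest.approx(
            quiet_trial.truth.config.tidal_volume, rel=0.02
        )

    def test_short_gap_interpolated_long_gap_invalidates(self, default_grid):
        pts = cylinder_markers(140.0, 450.0, 4, 8)
        pos = np.repeat(pts[None], 200, axis=0).astype(float)
        pos[50:55, 3, :] = np.nan  # 5-sample gap: filled
        pos[100:140, 7, :] = np.nan  # 40-sample gap: invalid frames
        m = MarkerTrajectorySet(default_grid.labels, pos, 100.0)
        series = volume_series(m, default_grid)
        assert series.valid_mask[50:55].all()
        assert not series.valid_mask[100:140].any()

    def test_poor_coverage_reports_worst_markers(self, default_grid):
        pts = cylinder_markers(140.0, 450.0, 4, 8)
        pos = np.repeat(pts[None], 100, axis=0).astype(float)
        pos[10:90, 0, :] = np.nan
        m = MarkerTrajectorySet(default_grid.labels, pos, 100.0)
        with pytest.raises(ValueError, match="CW_0_0"):
            volume_series(m, default_grid)
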