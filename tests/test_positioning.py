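"""Scalp geodesics, placement sheet and repositioning simulation."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from _oracles import mc_nearest_distance_to_line
from repe import phantom, positioning, shaping
from repe.core import BinaryMask, FiducialSet, SulcusTrace
from repe.errors import ParameterError, PlacementError, ProjectionError


class TestGeodesicDistance:
    def test_same_point_zero(self, sphere_surf4):
        p = sphere_surf4.vertices[0]
        assert positioning.geodesic_distance(sphere_surf4, p, p) == 0.0

    def test_symmetric(self, sphere_surf4):
        a = sphere_surf4.vertices[10]
        b = sphere_surf4.vertices[2000]
        dab = positioning.geodesic_distance(sphere_surf4, a, b)
        dba = positioning.geodesic_distance(sphere_surf4, b, a)
        # same undirected path; only float summation order can differ
        assert dab == pytest.approx(dba, abs=1e-9)

    def test_antipodal_within_8_percent_of_great_circle(self, sphere_surf4):
        top = np.array([0.0, 0.0, 40.0])
        bottom = np.array([0.0, 0.0, -40.0])
        d = positioning.geodesic_distance(sphere_surf4, top, bottom)
        exact = np.pi * 40.0
        assert 0.95 * exact < d < 1.08 * exact  # edge-graph overestimates

    def test_far_point_raises(self, sphere_surf4):
        with pytest.raises(ProjectionError):
            positioning.geodesic_distance(
                sphere_surf4, np.zeros(3), np.array([0, 0, 40.0])
            )


@pytest.fixture(scope="module")
def ball_setup(sphere_surf4):
    """Sphere with fiducials at the +-y poles and an electrode arc at the top."""
    fid = FiducialSet(nasion=[0, 40.0, 0], inion=[0, -40.0, 0])
    th = np.radians(np.linspace(-60, 60, 81))
    arc = np.stack([40 * np.sin(th), np.zeros_like(th), 40 * np.cos(th)], 1)
    arc, _, _ = shaping.closest_points_on_surface(sphere_surf4, arc)
    return fid, arc


class TestPlacementSheet:
    def test_sphere_quarter_circle(self, sphere_surf4, ball_setup):
        fid, arc = ball_setup
        sheet = positioning.compute_placement_sheet(sphere_surf4, fid, arc)
        quarter = np.pi * 40.0 / 2.0
        # edge-graph geodesics overestimate off-axis paths by up to ~12%
        assert sheet.d_N_C == pytest.approx(quarter, rel=0.15)
        assert sheet.d_NI == pytest.approx(2 * quarter, rel=0.08)

    def test_symmetry_left_right(self, sphere_surf4, ball_setup):
        fid, arc = ball_setup
        sheet = positioning.compute_placement_sheet(sphere_surf4, fid, arc)
        assert abs(sheet.d_N_L - sheet.d_N_R) < 2.0

    def test_center_before_inion(self, sphere_surf4, ball_setup):
        fid, arc = ball_setup
        sheet = positioning.compute_placement_sheet(sphere_surf4, fid, arc)
        assert sheet.d_N_C < sheet.d_NI

    def test_phantom_placement(self, surf2, pair2, icss2):
        sheet = positioning.compute_placement_sheet(
            surf2, pair2.truth.fiducials, icss2.dedupe().points, tol_mm=4.0
        )
        assert 0 < sheet.d_N_C < sheet.d_NI
        assert abs(sheet.d_N_L - sheet.d_N_R) < 8.0

    def test_off_midline_footprint_rejected(self, sphere_surf4, ball_setup):
        fid, _ = ball_setup
        # an arc hugging the equator far from the N-I midline
        th = np.radians(np.linspace(-30, 30, 31))
        arc = np.stack(
            [40 * np.cos(th), 40 * np.sin(th), np.zeros_like(th)], 1
        )  # x-y plane, nearest midline approach ~ 35 mm
        arc = arc + np.array([0.0, 0.0, 0.0])
        with pytest.raises(PlacementError):
            positioning.compute_placement_sheet(
                sphere_surf4, fid, arc, max_midline_offset_mm=10.0
            )


class TestMarkerPoints:
    def test_27_markers_at_5mm(self, icss2):
        pts = positioning.electrode_marker_points(icss2.dedupe().points)
        assert pts.shape == (27, 3)
        # arc-length spacing is exactly 5 mm by construction; chords are a bit
        # shorter where the projected polyline zigzags at mesh resolution
        spacing = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        assert np.all((spacing > 3.0) & (spacing < 5.5))
        straight = np.stack([np.arange(0, 140, 1.0), np.zeros(140), np.zeros(140)], 1)
        exact = positioning.electrode_marker_points(straight)
        assert np.allclose(
            np.linalg.norm(np.diff(exact, axis=0), axis=1), 5.0, atol=1e-9
        )

    def test_too_short_footprint_raises(self):
        short = np.stack([np.linspace(0, 50, 20), np.zeros(20), np.zeros(20)], 1)
        with pytest.raises(PlacementError):
            positioning.electrode_marker_points(short)


class TestSimulateRepositioning:
    def test_zero_noise_equals_truth(self, icss2):
        fp = icss2.dedupe().points
        reps = positioning.simulate_repositioning(fp, 3, noise_sd_mm=0.0, seed=1)
        gt = positioning.electrode_marker_points(fp)
        for rep in reps:
            assert np.array_equal(rep, gt)

    def test_same_seed_identical(self, icss2):
        fp = icss2.dedupe().points
        a = positioning.simulate_repositioning(fp, 4, seed=9)
        b = positioning.simulate_repositioning(fp, 4, seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_halfnormal_mean_displacement(self, icss2):
        """Mean |noise| before snapping ~ sigma*sqrt(8/pi) (3D half-normal)."""
        fp = icss2.dedupe().points
        sigma = 2.0
        reps = positioning.simulate_repositioning(
            fp, 300, noise_sd_mm=sigma, seed=4, surf=None
        )
        gt = positioning.electrode_marker_points(fp)
        d = np.linalg.norm(np.concatenate(reps) - np.tile(gt, (300, 1)), axis=1)
        expected = sigma * np.sqrt(8 / np.pi)
        assert d.mean() == pytest.approx(expected, rel=0.03)

    def test_invalid_params(self, icss2):
        fp = icss2.dedupe().points
        with pytest.raises(ParameterError):
            positioning.simulate_repositioning(fp, 0)
        with pytest.raises(ParameterError):
            positioning.simulate_repositioning(fp, 1, noise_sd_mm=-1.0)


class TestPositioningError:
    def test_identity_zero(self, icss2):
        ref = icss2.dedupe()
        reps = [positioning.electrode_marker_points(ref.points)]
        # markers resampled on the polyline are not exactly reference points;
        # use the reference samples themselves as the "repetition"
        report = positioning.positioning_error([ref.points], ref)
        assert report.overall_mean_mm == 0.0

    def test_3_4_5_offset(self):
        ref_pts = np.stack(
            [np.arange(0, 200, 1.0), np.zeros(200), np.zeros(200)], 1
        )
        ref = SulcusTrace(ref_pts, "scalp")
        rep = ref_pts[50:77].copy() + np.array([0.0, 3.0, 4.0])
        report = positioning.positioning_error([rep], ref)
        assert report.overall_mean_mm == pytest.approx(5.0)
        assert report.axis_mean_mm[0] == pytest.approx([0.0, 3.0, 4.0])

    def test_overall_mean_is_mean_of_rep_means(self, icss2):
        fp = icss2.dedupe().points
        reps = positioning.simulate_repositioning(fp, 5, noise_sd_mm=2.0, seed=2)
        report = positioning.positioning_error(reps, icss2.dedupe())
        assert report.overall_mean_mm == pytest.approx(
            report.per_rep_mean_mm.mean()
        )

    def test_simulated_error_matches_mc_oracle(self, icss2):
        """sigma=2 mm/axis, 5 reps, 27 markers: within 15% of the MC oracle."""
        ref = icss2.dedupe()
        sigma = 2.0
        reps = positioning.simulate_repositioning(
            ref.points, 5, noise_sd_mm=sigma, seed=11, surf=None
        )
        report = positioning.positioning_error(reps, ref)
        spacing = ref.length / (len(ref) - 1)
        oracle = mc_nearest_distance_to_line(sigma, spacing)
        assert report.overall_mean_mm == pytest.approx(oracle, rel=0.15)

    def test_empty_reference_rejected(self, icss2):
        with pytest.raises(ParameterError):
            positioning.positioning_error([], icss2)
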