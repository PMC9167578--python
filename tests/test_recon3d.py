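"""Geometry reconstruction: transforms, areas, volume, invariances."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from tendonmech import recon3d, synthgen
from tendonmech.recon3d import (
    CalibrationTransform,
    ContourSlice,
    Pose,
    TrackedSweep,
    contour_area,
    mean_csa,
    pixel_to_world,
    reconstruct_geometry,
    reconstruct_volume,
    tendon_length,
)


def _random_pose(seed):
    rng = np.random.default_rng(seed)
    return Pose(
        Rotation.from_rotvec(rng.uniform(-np.pi, np.pi, 3)).as_matrix(),
        rng.uniform(-100, 100, 3),
    )


class TestPixelToWorld:
    def test_identity_composition_maps_origin(self):
        p = pixel_to_world((0, 0), CalibrationTransform.identity(), Pose.identity())
        np.testing.assert_allclose(p, [0.0, 0.0, 0.0])

    def test_pure_translation(self):
        pose = Pose(np.eye(3), [1.0, -2.0, 3.0])
        cal = CalibrationTransform.identity()
        base = pixel_to_world((5, 7), cal, Pose.identity())
        moved = pixel_to_world((5, 7), cal, pose)
        np.testing.assert_allclose(moved, base + [1.0, -2.0, 3.0])

    @given(st.integers(0, 1000))
    def test_isometry_under_random_pose(self, seed):
        """Two pixels 10 px apart at 0.1 mm/px are 1.0 mm apart in the world."""
        pose = _random_pose(seed)
        cal = CalibrationTransform(0.1, 0.1)
        a = pixel_to_world((0, 0), cal, pose)
        b = pixel_to_world((0, 10), cal, pose)
        assert np.linalg.norm(b - a) == pytest.approx(1.0, rel=1e-9)

    def test_non_orthonormal_rotation_rejected(self):
        with pytest.raises(ValueError):
            Pose(np.eye(3) * 2.0, np.zeros(3))


class TestTendonLength:
    def test_coincident_points(self):
        assert tendon_length([1, 2, 3], [1, 2, 3]) == 0.0

    def test_axis_aligned(self):
        assert tendon_length([0, 0, 0], [0, 0, 50]) == pytest.approx(50.0)

    def test_missing_landmark_names_site(self):
        with pytest.raises(ValueError, match="soleus"):
            tendon_length([0, 0, 0], None)
        with pytest.raises(ValueError, match="calcaneal"):
            tendon_length(None, [0, 0, 0])

    def test_noiseless_sweep_recovers_phantom_length(self, cylinder_phantom):
        sweep = synthgen.simulate_sweep(cylinder_phantom, seed=0)
        geom = reconstruct_geometry(sweep)
        assert geom.length_mm == pytest.approx(50.0, abs=0.01)


class TestContourArea:
    def test_unit_square(self):
        square = [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]]
        assert contour_area(square) == pytest.approx(1.0)

    def test_regular_polygon_closed_form(self):
        n, r = 64, 4.0
        theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
        poly = np.column_stack(
            [r * np.cos(theta), r * np.sin(theta), np.zeros(n)]
        )
        expected = (n / 2.0) * r**2 * math.sin(2 * math.pi / n)
        assert contour_area(poly) == pytest.approx(expected, rel=1e-12)

    def test_orientation_invariance(self):
        square = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
        assert contour_area(square) == pytest.approx(contour_area(square[::-1]))

    def test_self_intersecting_rejected(self):
        bowtie = [[0, 0, 0], [1, 1, 0], [1, 0, 0], [0, 1, 0]]
        with pytest.raises(ValueError, match="self-intersect"):
            contour_area(bowtie)

    def test_non_planar_rejected(self):
        # one corner lifted 4 mm: best-fit-plane deviation ~1 mm > 0.5 mm tol
        poly = [[0, 0, 0], [10, 0, 0], [10, 10, 4.0], [0, 10, 0]]
        with pytest.raises(ValueError, match="plane"):
            contour_area(poly)


def _square_slice(area_mm2, station):
    half = math.sqrt(area_mm2) / 2.0
    verts = np.array(
        [
            [-half, -half, station],
            [half, -half, station],
            [half, half, station],
            [-half, half, station],
        ]
    )
    return ContourSlice(verts, station)


class TestVolumeAndMeanCsa:
    def test_constant_area_prism(self):
        slices = [_square_slice(50.0, 0.0), _square_slice(50.0, 50.0)]
        assert reconstruct_volume(slices) == pytest.approx(2.5, rel=1e-9)

    def test_trapezoid_exact_for_linear_taper(self):
        # linear 60 -> 40 mm^2 over 60 mm, slices every 5 mm -> exactly 3 ml
        stations = np.arange(0.0, 60.0 + 1e-9, 5.0)
        areas = 60.0 + (40.0 - 60.0) * stations / 60.0
        slices = [_square_slice(a, s) for a, s in zip(areas, stations)]
        assert reconstruct_volume(slices) == pytest.approx(3.0, rel=1e-9)
        assert mean_csa(slices) == pytest.approx(50.0, rel=1e-9)

    def test_unordered_stations_rejected(self):
        slices = [_square_slice(50.0, 10.0), _square_slice(50.0, 0.0)]
        with pytest.raises(ValueError, match="increasing"):
            reconstruct_volume(slices)

    def test_duplicate_stations_rejected(self):
        slices = [_square_slice(50.0, 0.0), _square_slice(50.0, 0.0)]
        with pytest.raises(ValueError, match="increasing"):
            reconstruct_volume(slices)

    def test_mean_csa_needs_a_slice(self):
        with pytest.raises(ValueError):
            mean_csa([])

    @given(st.integers(0, 500))
    def test_mean_csa_volume_identity(self, seed):
        """mean CSA x station span / 1000 equals the volume, exactly."""
        rng = np.random.default_rng(seed)
        stations = np.sort(rng.uniform(0, 80, 6))
        stations += np.arange(6) * 1e-3  # ensure strictly increasing
        slices = [
            _square_slice(a, s)
            for a, s in zip(rng.uniform(30, 70, 6), stations)
        ]
        span = stations[-1] - stations[0]
        assert mean_csa(slices) * span / 1000.0 == pytest.approx(
            reconstruct_volume(slices), rel=1e-12
        )

    def test_volume_converges_with_finer_slicing(self):
        phantom = synthgen.make_phantom(60.0, ("quadratic", 40.0, 30.0, -20.0))
        errors = []
        for spacing in (10.0, 5.0, 1.0, 0.2):
            sweep = synthgen.simulate_sweep(
                phantom, frame_spacing_mm=spacing, contour_points=256, seed=0
            )
            geom = reconstruct_geometry(sweep, step_mm=0.1)
            errors.append(abs(geom.volume_ml - phantom.true_volume_ml))
        assert errors == sorted(errors, reverse=True)


class TestRigidInvariance:
    def test_whole_sweep_rigid_motion_leaves_measures_unchanged(
        self, cylinder_phantom
    ):
        sweep = synthgen.simulate_sweep(
            cylinder_phantom, frame_spacing_mm=1.0, seed=0
        )
        geom = reconstruct_geometry(sweep, step_mm=0.5)
        motion = _random_pose(123)
        moved = TrackedSweep(
            [
                recon3d.Frame(
                    Pose(
                        motion.rotation @ f.pose.rotation,
                        motion.apply(f.pose.translation),
                    ),
                    f.contour_px,
                    f.landmark,
                )
                for f in sweep.frames
            ],
            sweep.calibration,
        )
        geom2 = reconstruct_geometry(moved, step_mm=0.5)
        assert geom2.length_mm == pytest.approx(geom.length_mm, rel=1e-9)
        assert geom2.volume_ml == pytest.approx(geom.volume_ml, rel=1e-9)
        assert geom2.mean_csa_mm2 == pytest.approx(geom.mean_csa_mm2, rel=1e-9)


class TestReconstructGeometry:
    def test_noiseless_cylinder_volume_within_one_percent(self, cylinder_phantom):
        sweep = synthgen.simulate_sweep(
            cylinder_phantom, frame_spacing_mm=0.1, contour_points=64, seed=0
        )
        geom = reconstruct_geometry(sweep)
        assert geom.volume_ml == pytest.approx(
            cylinder_phantom.true_volume_ml, rel=0.01
        )

    def test_sparse_contouring_interval(self, cylinder_phantom):
        sweep = synthgen.simulate_sweep(
            cylinder_phantom, frame_spacing_mm=0.5, seed=0
        )
        geom = reconstruct_geometry(sweep, slice_interval_mm=5.0)
        # 5 mm intervals over 50 mm -> 11 retained slices
        assert len(geom.slices) == 11
        assert geom.volume_ml == pytest.approx(
            cylinder_phantom.true_volume_ml, rel=0.01
        )
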