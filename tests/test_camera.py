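"""Camera model, homography, planar PnP, ray intersection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from planegaze import (
    CameraCalibration,
    GeometryError,
    Homography,
    Pose,
    angular_from_plane_point,
    apply_homography,
    estimate_homography,
    estimate_pose,
    intersect_gaze_ray,
    plane_to_pixel,
    project_point,
    undistort_point,
)
from planegaze.camera import distort_normalized

from .conftest import random_pose


# ---------------------------------------------------------------- distortion

class TestUndistort:
    def test_principal_point_maps_to_origin(self, calib):
        assert np.allclose(undistort_point((640, 360), calib), (0, 0))

    def test_zero_distortion_is_linear_pinhole(self, calib):
        assert np.allclose(undistort_point((740, 360), calib), (0.1, 0.0))

    def test_radial_distortion_inverted(self):
        # forward model of (0.2, 0) with k1=-0.1: r^2=0.04, scale 0.996,
        # x_d = 0.1992 -> pixel 839.2; inversion must recover (0.2, 0)
        c = CameraCalibration(1000, 1000, 640, 360, 1280, 720, k1=-0.1)
        xy = undistort_point((839.2, 360.0), c)
        assert np.allclose(xy, (0.2, 0.0), atol=1e-6)

    def test_forward_backward_consistency(self):
        c = CameraCalibration(
            900, 910, 640, 360, 1280, 720,
            k1=-0.11, k2=0.03, k3=-0.004, p1=0.0005, p2=-0.0003,
        )
        rng = np.random.default_rng(0)
        px = rng.uniform([200, 150], [1080, 570], size=(50, 2))
        for p in px:
            xy = undistort_point(p, c)
            xd = distort_normalized(xy, c)
            back = np.array([c.fx * xd[0] + c.cx, c.fy * xd[1] + c.cy])
            assert np.allclose(back, p, atol=1e-6)

    def test_nonfinite_pixel_rejected(self, calib):
        with pytest.raises(GeometryError):
            undistort_point((np.nan, 10.0), calib)


class TestCalibration:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            CameraCalibration(-1, 1000, 640, 360, 1280, 720)
        with pytest.raises(ValueError):
            CameraCalibration(1000, 1000, 2000, 360, 1280, 720)

    def test_file_round_trip(self, tmp_path):
        c = CameraCalibration(1000, 1001, 640, 360, 1280, 720, k1=-0.1, p1=1e-4)
        c.to_file(tmp_path / "calib.txt")
        assert CameraCalibration.from_file(tmp_path / "calib.txt") == c

    def test_missing_keys_rejected(self, tmp_path):
        (tmp_path / "bad.txt").write_text("fx = 1000\n")
        with pytest.raises(ValueError, match="missing"):
            CameraCalibration.from_file(tmp_path / "bad.txt")


# ---------------------------------------------------------------- projection

class TestProjection:
    def test_on_axis_point_hits_principal_point(self, calib, fronto_pose):
        assert np.allclose(project_point((0, 0), fronto_pose, calib), (640, 360))

    def test_pinhole_closed_form(self, calib, fronto_pose):
        # x_px = cx + fx * 50/500
        assert np.allclose(project_point((50, 0), fronto_pose, calib), (740, 360))

    def test_point_behind_camera_rejected(self, calib):
        with pytest.raises(GeometryError, match="behind"):
            project_point((0, 0), Pose(np.eye(3), (0, 0, -500.0)), calib)


# ---------------------------------------------------------------- homography

class TestHomography:
    def test_identity_from_equal_correspondences(self):
        pts = np.array([[0.0, 0], [100, 0], [100, 100], [0, 100]])
        H = estimate_homography(pts, pts)
        assert np.allclose(H.H, np.eye(3), atol=1e-9)

    def test_pure_scale(self):
        pts = np.array([[0.0, 0], [100, 0], [100, 100], [0, 100]])
        H = estimate_homography(pts, 2 * pts)
        assert np.allclose(H.H, np.diag([2.0, 2.0, 1.0]), atol=1e-9)

    def test_recovers_random_generator(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            Htrue = np.eye(3) + rng.uniform(-0.1, 0.1, (3, 3))
            Htrue[2, 2] = 1.0
            if np.linalg.cond(Htrue) > 1e3:
                continue
            src = rng.uniform(-200, 200, (8, 2))
            dst = apply_homography(Homography(Htrue), src)
            Hest = estimate_homography(src, dst)
            rel = np.linalg.norm(Hest.H - Htrue) / np.linalg.norm(Htrue)
            assert rel < 1e-9
            assert Hest.rms < 1e-9

    def test_matches_skimage_oracle(self):
        skimage_tf = pytest.importorskip("skimage.transform")
        rng = np.random.default_rng(9)
        src = rng.uniform(0, 1000, (10, 2))
        Htrue = np.array([[1.1, 0.02, 5.0], [-0.03, 0.95, -7.0], [1e-4, -2e-4, 1.0]])
        dst = apply_homography(Homography(Htrue), src) + rng.normal(0, 0.3, (10, 2))
        ours = estimate_homography(src, dst).H
        theirs = skimage_tf.ProjectiveTransform.from_estimate(src, dst)
        ref = theirs.params / theirs.params[2, 2]
        assert np.allclose(ours, ref, atol=1e-6)

    def test_too_few_correspondences(self):
        pts = np.array([[0.0, 0], [1, 0], [0, 1]])
        with pytest.raises(GeometryError, match="insufficient"):
            estimate_homography(pts, pts)

    def test_collinear_points_degenerate(self):
        src = np.array([[0.0, 0], [1, 0], [2, 0], [3, 0], [4, 0]])
        with pytest.raises(GeometryError, match="degenerate"):
            estimate_homography(src, src)

    def test_apply_matches_direct_matrix_multiply(self):
        rng = np.random.default_rng(2)
        H = np.eye(3) + rng.uniform(-0.2, 0.2, (3, 3))
        H[2, 2] = 1.0
        h = Homography(H)
        for p in rng.uniform(-100, 100, (20, 2)):
            v = H @ np.array([p[0], p[1], 1.0])
            assert np.allclose(apply_homography(h, p), v[:2] / v[2], atol=1e-12)

    def test_inverse_round_trips(self):
        H = Homography(np.array([[2.0, 0.1, 3], [0, 1.5, -2], [1e-4, 0, 1]]))
        p = np.array([37.0, -11.0])
        assert np.allclose(apply_homography(H.inverse(), apply_homography(H, p)), p,
                           atol=1e-9)

    def test_singular_matrix_rejected(self):
        with pytest.raises(GeometryError):
            Homography(np.array([[1.0, 0, 0], [1, 0, 0], [0, 0, 1]]))


# ---------------------------------------------------------------- planar PnP

def _grid_corners(n=3, edge=40.0, spacing=100.0):
    """Corner coordinates of an n x n marker grid (plane mm)."""
    pts = []
    offs = (np.arange(n) - (n - 1) / 2) * spacing
    for cy in offs:
        for cx in offs:
            e = edge / 2
            pts += [[cx - e, cy - e], [cx + e, cy - e], [cx + e, cy + e], [cx - e, cy + e]]
    return np.array(pts)


class TestPoseEstimation:
    def test_recovers_fronto_parallel_pose(self, calib):
        truth = Pose(np.eye(3), (0, 0, 500.0))
        pts = _grid_corners()[:12]
        px = project_point(pts, truth, calib)
        pose, rms = estimate_pose(px, pts, calib)
        assert rms < 1e-6
        assert np.abs(pose.t - truth.t).max() < 1e-6
        assert np.abs(pose.R - np.eye(3)).max() < 1e-8

    def test_recovers_yawed_pose(self, wide_calib):
        c, s = math.cos(math.radians(20)), math.sin(math.radians(20))
        R = np.array([[c, 0, -s], [0, 1, 0], [s, 0, c]])
        truth = Pose(R, -R @ np.array([0, 0, -600.0]))
        pts = _grid_corners()
        px = project_point(pts, truth, wide_calib)
        pose, rms = estimate_pose(px, pts, wide_calib)
        yaw = math.degrees(math.atan2(pose.R[2, 0], pose.R[0, 0]))
        assert abs(yaw - 20.0) < 1e-6
        assert np.abs(pose.t - truth.t).max() < 1e-6

    def test_three_points_insufficient(self, calib):
        pts = _grid_corners()[:3]
        with pytest.raises(GeometryError, match="insufficient"):
            estimate_pose(np.array([[0, 0], [1, 0], [0, 1.0]]), pts, calib)

    def test_requires_calibration(self):
        with pytest.raises(GeometryError, match="unavailable"):
            estimate_pose(np.zeros((4, 2)), np.zeros((4, 2)), None)

    def test_distorted_camera_recovered(self):
        c = CameraCalibration(1000, 1000, 640, 360, 1280, 720, k1=-0.15, k2=0.02)
        rng = np.random.default_rng(4)
        truth = random_pose(rng)
        pts = _grid_corners()
        px = project_point(pts, truth, c)
        pose, rms = estimate_pose(px, pts, c)
        assert rms < 1e-6
        assert np.abs(pose.t - truth.t).max() < 1e-5


# ------------------------------------------------------------ ray intersection

class TestGazeRay:
    def test_principal_point_hits_plane_origin(self, calib, fronto_pose):
        assert np.allclose(intersect_gaze_ray((640, 360), fronto_pose, calib), (0, 0),
                           atol=1e-9)

    def test_similar_triangles_closed_form(self, calib, fronto_pose):
        # 100 px at f=1000 from 500 mm -> 50 mm on the plane
        assert np.allclose(intersect_gaze_ray((740, 360), fronto_pose, calib), (50, 0),
                           atol=1e-9)

    def test_edge_on_plane_rejected(self, calib):
        R = np.array([[0.0, 0, -1], [0, 1, 0], [1, 0, 0]])  # plane seen edge-on
        pose = Pose(R, np.array([0.0, 0.0, 500.0]))
        with pytest.raises(GeometryError, match="parallel"):
            intersect_gaze_ray((640, 360), pose, calib)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_project_intersect_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        calib = CameraCalibration(1000, 1000, 960, 540, 1920, 1080)
        pose = random_pose(rng)
        P = rng.uniform(-150, 150, 2)
        px = project_point(P, pose, calib)
        assert np.abs(intersect_gaze_ray(px, pose, calib) - P).max() < 1e-6


# ------------------------------------------------------------ inverse mapping

class TestPlaneToPixel:
    def test_identity_homography(self):
        H = Homography(np.eye(3))
        assert np.allclose(plane_to_pixel((15, 25), homography=H), (15, 25))

    def test_pose_path_is_projection(self, calib, fronto_pose):
        assert np.allclose(plane_to_pixel((50, 0), pose=fronto_pose, calib=calib),
                           (740, 360))

    def test_round_trip_100_points(self, wide_calib):
        rng = np.random.default_rng(6)
        pose = random_pose(rng)
        pts = rng.uniform(-150, 150, (100, 2))
        px = project_point(pts, pose, wide_calib)
        back = np.array([intersect_gaze_ray(p, pose, wide_calib) for p in px])
        assert np.abs(back - pts).max() < 1e-6

    def test_requires_some_geometry(self):
        with pytest.raises(GeometryError, match="no geometry"):
            plane_to_pixel((0, 0))


# ---------------------------------------------------------------- angular

class TestAngularGaze:
    def test_on_axis_is_zero(self):
        pose = Pose(np.eye(3), (0, 0, 600.0))
        a = angular_from_plane_point((0, 0), pose)
        assert a.azimuth == 0 and a.elevation == 0

    def test_one_degree_azimuth(self):
        pose = Pose(np.eye(3), (0, 0, 600.0))
        a = angular_from_plane_point((10.47, 0), pose)
        assert abs(a.azimuth - 1.0) < 1e-3

    def test_45_degree_elevation(self):
        pose = Pose(np.eye(3), (0, 0, 600.0))
        a = angular_from_plane_point((0, -600), pose)
        assert abs(a.elevation - (-45.0)) < 1e-9

    def test_behind_viewer_rejected(self):
        pose = Pose(np.eye(3), (0, 0, -600.0))
        with pytest.raises(GeometryError, match="behind"):
            angular_from_plane_point((0, 0), pose)


# ------------------------------------------------------- cross-method checks

@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 10_000))
def test_homography_and_pose_paths_agree_without_distortion(seed):
    """The two gaze-mapping routes are interchangeable on an ideal camera."""
    rng = np.random.default_rng(seed)
    calib = CameraCalibration(1000, 1000, 960, 540, 1920, 1080)
    pose = random_pose(rng)
    pts = _grid_corners()
    px = project_point(pts, pose, calib)
    H = estimate_homography(px, pts)
    gaze = project_point(rng.uniform(-120, 120, 2), pose, calib)
    via_h = apply_homography(H, gaze)
    via_p = intersect_gaze_ray(gaze, pose, calib)
    assert np.abs(via_h - via_p).max() < 1e-3


def test_pose_invariants_enforced():
    with pytest.raises(ValueError, match="orthonormal"):
        Pose(np.eye(3) * 1.1, np.zeros(3))
    with pytest.raises(ValueError, match="determinant"):
        Pose(np.diag([1.0, 1.0, -1.0]), np.zeros(3))
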