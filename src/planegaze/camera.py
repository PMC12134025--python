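"""Camera model and the two gaze-transformation geometries.

A wearable eye tracker reports gaze in pixels on its head-fixed scene
video.  To express gaze on a flat world surface ("plane") two routes
exist:

* **Homography** — a 3x3 projective map between the scene image and the
  plane, estimated directly from marker-corner correspondences.  Needs
  no camera calibration provided lens distortion is negligible.
* **Pose + ray intersection** — with a calibrated camera, the camera's
  pose relative to the plane is recovered from the same correspondences
  (a planar Perspective-n-Point problem) and the gaze pixel's
  back-projected ray is intersected with the plane.

Conventions: pixel coordinates are 0-based, origin top-left, x right,
y down.  Plane coordinates are in mm, x right, y down, origin at the
plane centre.  A :class:`Pose` maps plane-frame points to the camera
frame; for a camera in front of the plane the plane origin has positive
camera-frame z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "CameraCalibration",
    "Pose",
    "Homography",
    "AngularGaze",
    "GeometryError",
    "undistort_point",
    "distort_normalized",
    "project_point",
    "estimate_homography",
    "apply_homography",
    "estimate_pose",
    "intersect_gaze_ray",
    "plane_to_pixel",
    "angular_from_plane_point",
]


class GeometryError(ValueError):
    """Raised for degenerate or non-invertible geometric configurations."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CameraCalibration:
    """Pinhole intrinsics plus Brown–Conrady distortion.

    ``fx, fy`` focal lengths and ``cx, cy`` principal point are in
    pixels; ``w, h`` is the image size.  ``k1, k2, k3`` are radial and
    ``p1, p2`` tangential distortion coefficients (dimensionless).
    All-zero distortion reduces every operation to the ideal pinhole
    model exactly.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    w: int
    h: int
    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    p1: float = 0.0
    p2: float = 0.0

    def __post_init__(self) -> None:
        if not (self.fx > 0 and self.fy > 0):
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.w and 0 <= self.cy < self.h):
            raise ValueError("principal point must lie inside the image")

    @property
    def has_distortion(self) -> bool:
        return any(getattr(self, n) != 0.0 for n in ("k1", "k2", "k3", "p1", "p2"))

    @property
    def K(self) -> np.ndarray:
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )

    # -- plain-text key=value dialect ------------------------------------
    def to_file(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# camera calibration (pinhole + Brown-Conrady)\n")
            for f in fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)!r}\n")

    @classmethod
    def from_file(cls, path) -> "CameraCalibration":
        vals: dict[str, float] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, raw = line.partition("=")
                vals[key.strip()] = float(raw.strip())
        missing = {"fx", "fy", "cx", "cy", "w", "h"} - vals.keys()
        if missing:
            raise ValueError(f"calibration file missing keys: {sorted(missing)}")
        vals["w"] = int(vals["w"])
        vals["h"] = int(vals["h"])
        return cls(**vals)  # type: ignore[arg-type]


@dataclass(frozen=True)
class Pose:
    """Rigid transform from plane frame to camera frame: X_cam = R @ X_plane + t.

    ``t`` is the plane origin expressed in the camera frame (mm).
    """

    R: np.ndarray
    t: np.ndarray
    ambiguous: bool = False

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float).reshape(3, 3)
        t = np.asarray(self.t, dtype=float).reshape(3)
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "t", t)
        if np.max(np.abs(R @ R.T - np.eye(3))) > 1e-9:
            raise ValueError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation matrix determinant is not +1")

    @property
    def camera_center(self) -> np.ndarray:
        """Camera optical centre in plane coordinates (mm)."""
        return -self.R.T @ self.t


@dataclass(frozen=True)
class Homography:
    """3x3 projective map from scene-image pixels to plane mm.

    Stored normalized with H[2, 2] == 1.
    """

    H: np.ndarray
    rms: float = 0.0

    def __post_init__(self) -> None:
        H = np.asarray(self.H, dtype=float).reshape(3, 3)
        if abs(H[2, 2]) < 1e-300 or abs(np.linalg.det(H / np.abs(H).max())) < 1e-12:
            raise GeometryError("homography is singular")
        object.__setattr__(self, "H", H / H[2, 2])

    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.H), rms=self.rms)


@dataclass(frozen=True)
class AngularGaze:
    """Gaze direction in the viewing frame: azimuth and elevation, degrees."""

    azimuth: float
    elevation: float


# --------------------------------------------------------------------------
# distortion model
# --------------------------------------------------------------------------

def distort_normalized(xy, calib: CameraCalibration) -> np.ndarray:
    """Apply the Brown–Conrady forward model to normalized image coords."""
    xy = np.asarray(xy, dtype=float)
    x, y = xy[..., 0], xy[..., 1]
    r2 = x * x + y * y
    radial = 1.0 + r2 * (calib.k1 + r2 * (calib.k2 + r2 * calib.k3))
    xd = x * radial + 2.0 * calib.p1 * x * y + calib.p2 * (r2 + 2.0 * x * x)
    yd = y * radial + calib.p1 * (r2 + 2.0 * y * y) + 2.0 * calib.p2 * x * y
    return np.stack([xd, yd], axis=-1)


def undistort_point(p, calib: CameraCalibration) -> np.ndarray:
    """Pixel coordinates -> undistorted normalized image coordinates.

    Inverts the Brown–Conrady model by fixed-point iteration (tolerance
    1e-10 in normalized units, at most 50 iterations).  With zero
    distortion this is exactly ``((px-cx)/fx, (py-cy)/fy)``.
    """
    p = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(p)):
        raise GeometryError("non-finite pixel coordinates")
    xd = np.stack([(p[..., 0] - calib.cx) / calib.fx,
                   (p[..., 1] - calib.cy) / calib.fy], axis=-1)
    if not calib.has_distortion:
        return xd
    x = xd.copy()
    for _ in range(50):
        d = distort_normalized(x, calib)
        x_new = x + (xd - d)
        if np.max(np.abs(x_new - x)) < 1e-10:
            return x_new
        x = x_new
    raise GeometryError("point outside invertible region")


# --------------------------------------------------------------------------
# projection
# --------------------------------------------------------------------------

def _to_camera(P, pose: Pose) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    P3 = np.zeros(P.shape[:-1] + (3,))
    P3[..., : P.shape[-1]] = P
    return P3 @ pose.R.T + pose.t


def project_point(P, pose: Pose, calib: CameraCalibration) -> np.ndarray:
    """Project plane point(s) (X, Y) mm to pixel coordinates."""
    Xc = _to_camera(P, pose)
    z = Xc[..., 2]
    if np.any(z <= 0):
        raise GeometryError("not projectable: point behind camera")
    xy = Xc[..., :2] / z[..., None]
    xy = distort_normalized(xy, calib) if calib.has_distortion else xy
    return np.stack([calib.fx * xy[..., 0] + calib.cx,
                     calib.fy * xy[..., 1] + calib.cy], axis=-1)


# --------------------------------------------------------------------------
# homography estimation (Hartley-normalized DLT)
# --------------------------------------------------------------------------

def _hartley_normalization(pts: np.ndarray) -> np.ndarray:
    centroid = pts.mean(axis=0)
    d = np.sqrt(((pts - centroid) ** 2).sum(axis=1)).mean()
    s = math.sqrt(2.0) / d if d > 0 else 1.0
    return np.array(
        [[s, 0, -s * centroid[0]], [0, s, -s * centroid[1]], [0, 0, 1]]
    )


def estimate_homography(pixels, plane_mm, calib: CameraCalibration | None = None) -> Homography:
    """Estimate the pixel->plane homography from >=4 correspondences.

    When a calibration with distortion is supplied, pixels are
    undistorted first and the returned homography maps *undistorted*
    pixel coordinates (re-expressed through the intrinsics) to mm.
    Reprojection RMS (px-domain input units) is stored on the result.
    """
    src = np.asarray(pixels, dtype=float).reshape(-1, 2)
    dst = np.asarray(plane_mm, dtype=float).reshape(-1, 2)
    if src.shape[0] != dst.shape[0]:
        raise GeometryError("correspondence lists differ in length")
    if src.shape[0] < 4:
        raise GeometryError("insufficient correspondences: need >= 4")
    if calib is not None and calib.has_distortion:
        xy = undistort_point(src, calib)
        src = np.stack([calib.fx * xy[..., 0] + calib.cx,
                        calib.fy * xy[..., 1] + calib.cy], axis=-1)

    Ts, Td = _hartley_normalization(src), _hartley_normalization(dst)
    sh = np.hstack([src, np.ones((len(src), 1))]) @ Ts.T
    dh = np.hstack([dst, np.ones((len(dst), 1))]) @ Td.T

    A = np.zeros((2 * len(src), 9))
    for i, ((x, y, _), (u, v, _)) in enumerate(zip(sh, dh)):
        A[2 * i] = [-x, -y, -1, 0, 0, 0, u * x, u * y, u]
        A[2 * i + 1] = [0, 0, 0, -x, -y, -1, v * x, v * y, v]
    _, s, Vt = np.linalg.svd(A)
    if s[-2] < 1e-12 * s[0]:
        raise GeometryError("degenerate correspondences")
    Hn = Vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ Hn @ Ts
    if abs(H[2, 2]) < 1e-12:
        raise GeometryError("degenerate correspondences")
    H = H / H[2, 2]

    mapped = _apply_h(H, src)
    rms = float(np.sqrt(np.mean(np.sum((mapped - dst) ** 2, axis=1))))
    return Homography(H, rms=rms)


def _apply_h(H: np.ndarray, p: np.ndarray) -> np.ndarray:
    ph = np.concatenate([p, np.ones(p.shape[:-1] + (1,))], axis=-1)
    q = ph @ H.T
    w = q[..., 2]
    if np.any(np.abs(w) < 1e-12):
        raise GeometryError("unmappable point on the line at infinity")
    return q[..., :2] / w[..., None]


def apply_homography(H: Homography, p) -> np.ndarray:
    """Map pixel coordinates to plane mm with perspective division."""
    return _apply_h(H.H, np.asarray(p, dtype=float))


# --------------------------------------------------------------------------
# planar pose estimation (PnP)
# --------------------------------------------------------------------------

def _rotation_from_columns(r1: np.ndarray, r2: np.ndarray) -> np.ndarray:
    # nearest rotation to [r1 r2 r1xr2] in Frobenius norm
    M = np.column_stack([r1, r2, np.cross(r1, r2)])
    U, _, Vt = np.linalg.svd(M)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        R = U @ np.diag([1.0, 1.0, -1.0]) @ Vt
    return R


def _pose_candidates(pixels: np.ndarray, plane: np.ndarray, calib: CameraCalibration):
    """Initial pose guesses from the plane->normalized-image homography.

    The second candidate realizes the classic planar two-fold ambiguity:
    the plane normal reflected about the line of sight to the plane
    origin.
    """
    xy = undistort_point(pixels, calib)
    Hn = estimate_homography(plane, xy, None).H  # plane mm -> normalized image
    g1, g2, g3 = Hn[:, 0], Hn[:, 1], Hn[:, 2]
    lam = 2.0 / (np.linalg.norm(g1) + np.linalg.norm(g2))
    if g3[2] * lam < 0:  # plane origin must be in front of the camera
        lam = -lam
    R0 = _rotation_from_columns(lam * g1, lam * g2)
    t0 = lam * g3

    cands = [(R0, t0)]
    n = R0 @ np.array([0.0, 0.0, 1.0])
    d = t0 / np.linalg.norm(t0)
    n2 = 2.0 * float(n @ d) * d - n
    axis = np.cross(n, n2)
    s = np.linalg.norm(axis)
    if s > 1e-12:
        axis = axis / s
        ang = math.atan2(s, float(n @ n2))
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        Rflip = np.eye(3) + math.sin(ang) * K + (1 - math.cos(ang)) * (K @ K)
        cands.append((Rflip @ R0, t0.copy()))
    return cands


def _rodrigues(rvec: np.ndarray) -> np.ndarray:
    th = np.linalg.norm(rvec)
    if th < 1e-16:
        return np.eye(3)
    a = rvec / th
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + math.sin(th) * K + (1 - math.cos(th)) * (K @ K)


def _rvec_of(R: np.ndarray) -> np.ndarray:
    # inverse Rodrigues
    cos = (np.trace(R) - 1.0) / 2.0
    cos = min(1.0, max(-1.0, cos))
    th = math.acos(cos)
    if th < 1e-12:
        return np.zeros(3)
    if math.pi - th < 1e-6:
        # axis from R + I column of largest norm
        M = R + np.eye(3)
        axis = M[:, np.argmax(np.sum(M * M, axis=0))]
        axis = axis / np.linalg.norm(axis)
        return th * axis
    axis = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    return th * axis / (2.0 * math.sin(th))


def estimate_pose(pixels, plane_mm, calib: CameraCalibration):
    """Recover camera pose w.r.t. the plane from >=4 coplanar correspondences.

    Solves the planar PnP problem: homography-based initialization, both
    planar-ambiguity branches refined with Levenberg–Marquardt on pixel
    reprojection error, lower-RMS solution returned.  Returns
    ``(Pose, rms_px)``; the pose is flagged ``ambiguous`` when the two
    branches differ by less than 1% in RMS.
    """
    if calib is None:
        raise GeometryError("pose method unavailable: camera calibration required")
    pixels = np.asarray(pixels, dtype=float).reshape(-1, 2)
    plane = np.asarray(plane_mm, dtype=float).reshape(-1, 2)
    if len(pixels) != len(plane):
        raise GeometryError("correspondence lists differ in length")
    if len(pixels) < 4:
        raise GeometryError("insufficient correspondences: need >= 4")

    def residual(params):
        pose = Pose(_rodrigues(params[:3]), params[3:])
        try:
            proj = project_point(plane, pose, calib)
        except GeometryError:
            return np.full(2 * len(plane), 1e6)
        return (proj - pixels).ravel()

    results = []
    for ci, (R0, t0) in enumerate(_pose_candidates(pixels, plane, calib)):
        x0 = np.concatenate([_rvec_of(R0), t0])
        if ci > 0 and results and results[0][0] < 1e-8:
            # first branch already explains the data to numerical precision;
            # the alternative branch cannot tie, so its initial residual is
            # enough to rule out ambiguity
            r = residual(x0)
            results.append((float(np.sqrt(np.mean(r**2) * 2.0)), x0))
            continue
        sol = least_squares(residual, x0, method="lm", xtol=1e-15, ftol=1e-15)
        rms = float(np.sqrt(np.mean(sol.fun**2) * 2.0))  # per-point, both coords
        results.append((rms, sol.x))
    results.sort(key=lambda r: r[0])
    rms, x = results[0]
    ambiguous = (
        len(results) > 1
        and results[1][0] > 0
        and (results[1][0] - rms) < 0.01 * max(results[1][0], 1e-12)
    )
    pose = Pose(_rodrigues(x[:3]), x[3:], ambiguous=bool(ambiguous))
    if pose.t[2] <= 0:
        raise GeometryError("pose places the plane behind the camera")
    return pose, rms


# --------------------------------------------------------------------------
# gaze ray intersection and inverse mapping
# --------------------------------------------------------------------------

def intersect_gaze_ray(gaze_px, pose: Pose, calib: CameraCalibration) -> np.ndarray:
    """Intersect the back-projected gaze ray with the plane z=0 (mm)."""
    xy = undistort_point(np.asarray(gaze_px, dtype=float), calib)
    d_cam = np.array([xy[0], xy[1], 1.0])
    d_pl = pose.R.T @ d_cam
    if abs(d_pl[2]) < 1e-9:
        raise GeometryError("no forward intersection: ray parallel to plane")
    C = pose.camera_center
    s = -C[2] / d_pl[2]
    if s <= 0:
        raise GeometryError("no forward intersection: plane behind camera")
    return (C + s * d_pl)[:2]


def plane_to_pixel(P, *, pose: Pose | None = None,
                   calib: CameraCalibration | None = None,
                   homography: Homography | None = None) -> np.ndarray:
    """Map a plane point (mm) to pixel coordinates.

    Uses the pose + projection path when ``pose`` and ``calib`` are
    given, otherwise the inverse-homography path.
    """
    if pose is not None and calib is not None:
        return project_point(P, pose, calib)
    if homography is not None:
        return _apply_h(np.linalg.inv(homography.H), np.asarray(P, dtype=float))
    raise GeometryError("no geometry available: need pose+calib or homography")


def angular_from_plane_point(P, pose: Pose) -> AngularGaze:
    """Azimuth/elevation (deg) of the direction from the viewing position to P.

    The viewing position is the camera optical centre.  Azimuth is
    atan2(x, z), elevation atan2(y, sqrt(x^2+z^2)) of the camera-frame
    direction vector.
    """
    v = _to_camera(np.asarray(P, dtype=float), pose)
    if v[2] <= 0:
        raise GeometryError("behind viewer")
    az = math.degrees(math.atan2(v[0], v[2]))
    el = math.degrees(math.atan2(v[1], math.hypot(v[0], v[2])))
    return AngularGaze(az, el)
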