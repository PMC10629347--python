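"""Pinhole camera geometry: projection, distortion, triangulation, resectioning.

Conventions
-----------
* World frame: right-handed, origin at the arena-floor centre, +z up.
* Camera frame: +z along the optical axis, +x to the image right, +y down.
  Image origin is the top-left pixel corner; pixel coordinates are continuous.
* Extrinsics are stored world-to-camera: ``X_cam = R @ X_world + t``.
* All 3D quantities are millimetres; all image quantities are pixels.
* Distortion is the 5-coefficient radial-tangential model (k1, k2, p1, p2, k3)
  applied to normalised image coordinates. Fisheye lenses are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation
import scipy.linalg

from .detections import DetectionSet, Pose3DSeries

__all__ = [
    "BehindCameraError",
    "Camera",
    "CameraIntrinsics",
    "CameraPose",
    "ConfigurationError",
    "ConvergenceError",
    "DegenerateGeometryError",
    "Point3DEstimate",
    "RigCalibration",
    "RigRefinementReport",
    "distort_normalized",
    "project",
    "project_safe",
    "refine_rig",
    "resect",
    "triangulate",
    "triangulate_series",
    "undistort",
]

#: default orthonormality tolerance for rotation matrices
ORTHONORMAL_TOL = 1e-9


class BehindCameraError(ValueError):
    """A world point has non-positive depth in the camera frame."""


class DegenerateGeometryError(ValueError):
    """The camera/point configuration admits no unique solution."""


class ConvergenceError(RuntimeError):
    """An iterative numeric routine failed to converge within its cap."""


class ConfigurationError(ValueError):
    """A camera subset or option refers to something that does not exist."""


def _vec(x, n: int, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float).reshape(-1)
    if a.size != n:
        raise ValueError(f"{name} must have {n} elements, got {a.size}")
    return a


@dataclass(frozen=True)
class CameraIntrinsics:
    """Internal camera parameters.

    Focal lengths and principal point are in pixels; ``distortion`` holds the
    radial-tangential coefficients (k1, k2, p1, p2, k3).
    """

    focal_u: float
    focal_v: float
    principal_u: float
    principal_v: float
    skew: float = 0.0
    distortion: np.ndarray = field(default_factory=lambda: np.zeros(5))
    image_width: int = 1280
    image_height: int = 800

    def __post_init__(self):
        if self.focal_u <= 0 or self.focal_v <= 0:
            raise ValueError("focal lengths must be positive")
        if self.image_width <= 0 or self.image_height <= 0:
            raise ValueError("image dimensions must be positive")
        d = _vec(self.distortion, 5, "distortion").copy()
        d.setflags(write=False)
        object.__setattr__(self, "distortion", d)

    @property
    def matrix(self) -> np.ndarray:
        """3x3 intrinsic matrix K."""
        return np.array(
            [
                [self.focal_u, self.skew, self.principal_u],
                [0.0, self.focal_v, self.principal_v],
                [0.0, 0.0, 1.0],
            ]
        )

    @property
    def principal_point(self) -> np.ndarray:
        return np.array([self.principal_u, self.principal_v])


@dataclass(frozen=True)
class CameraPose:
    """World-to-camera rigid transform: ``X_cam = rotation @ X_world + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3).copy()
        t = _vec(self.translation, 3, "translation").copy()
        if not np.allclose(R @ R.T, np.eye(3), atol=ORTHONORMAL_TOL):
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > ORTHONORMAL_TOL * 10:
            raise ValueError("rotation must be proper (det +1)")
        R.setflags(write=False)
        t.setflags(write=False)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @property
    def camera_center(self) -> np.ndarray:
        """Optical centre in world coordinates, ``-R.T @ t``."""
        return -self.rotation.T @ self.translation

    def as_rotvec(self) -> np.ndarray:
        """Rodrigues axis-angle vector of the world-to-camera rotation."""
        return Rotation.from_matrix(self.rotation).as_rotvec()

    @classmethod
    def from_rotvec(cls, rotvec, translation) -> "CameraPose":
        R = Rotation.from_rotvec(np.asarray(rotvec, dtype=float)).as_matrix()
        return cls(R, translation)


@dataclass(frozen=True)
class Camera:
    """A calibrated camera: identity, intrinsics and pose."""

    camera_id: str
    intrinsics: CameraIntrinsics
    pose: CameraPose

    def project(self, points_world) -> np.ndarray:
        return project(self, points_world)


@dataclass
class RigCalibration:
    """An ordered collection of calibrated cameras sharing one world frame (mm)."""

    cameras: list[Camera]
    units_note: str = "mm"

    def __post_init__(self):
        if len(self.cameras) < 2:
            raise ValueError("a rig needs at least 2 cameras")
        ids = [c.camera_id for c in self.cameras]
        if len(set(ids)) != len(ids):
            raise ValueError("camera_id values must be unique within a rig")
        centers = np.array([c.pose.camera_center for c in self.cameras])
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                if np.linalg.norm(centers[i] - centers[j]) <= 1e-6:
                    raise ValueError(
                        f"cameras {ids[i]} and {ids[j]} share an optical centre"
                    )

    @property
    def camera_ids(self) -> list[str]:
        return [c.camera_id for c in self.cameras]

    def __len__(self) -> int:
        return len(self.cameras)

    def __getitem__(self, key) -> Camera:
        if isinstance(key, str):
            for c in self.cameras:
                if c.camera_id == key:
                    return c
            raise KeyError(key)
        return self.cameras[key]

    def subset(self, camera_ids: Sequence[str]) -> list[Camera]:
        unknown = set(camera_ids) - set(self.camera_ids)
        if unknown:
            raise ConfigurationError(f"unknown camera ids: {sorted(unknown)}")
        return [self[cid] for cid in camera_ids]


@dataclass
class Point3DEstimate:
    """A triangulated world point with its view count and reprojection RMS (px)."""

    coordinates: np.ndarray
    n_cameras_used: int
    reprojection_rms: float
    valid: bool

    def __post_init__(self):
        self.coordinates = _vec(self.coordinates, 3, "coordinates")
        if self.valid and self.n_cameras_used < 2:
            raise ValueError("a valid estimate needs at least 2 cameras")
        if self.valid and not self.reprojection_rms >= 0:
            raise ValueError("a valid estimate needs reprojection_rms >= 0")


# ---------------------------------------------------------------------------
# distortion
# ---------------------------------------------------------------------------

def distort_normalized(intrinsics: CameraIntrinsics, xy) -> np.ndarray:
    """Apply radial-tangential distortion to normalised coordinates ``(..., 2)``."""
    xy = np.asarray(xy, dtype=float)
    k1, k2, p1, p2, k3 = intrinsics.distortion
    x, y = xy[..., 0], xy[..., 1]
    r2 = x * x + y * y
    radial = 1.0 + r2 * (k1 + r2 * (k2 + r2 * k3))
    xd = x * radial + 2.0 * p1 * x * y + p2 * (r2 + 2.0 * x * x)
    yd = y * radial + p1 * (r2 + 2.0 * y * y) + 2.0 * p2 * x * y
    return np.stack([xd, yd], axis=-1)


def _distortion_jacobian(intrinsics: CameraIntrinsics, x, y):
    """Jacobian of the distortion map at normalised (x, y); returns 4 arrays
    (dxd/dx, dxd/dy, dyd/dx, dyd/dy) broadcasting with the inputs."""
    k1, k2, p1, p2, k3 = intrinsics.distortion
    r2 = x * x + y * y
    radial = 1.0 + r2 * (k1 + r2 * (k2 + r2 * k3))
    dradial = k1 + 2.0 * k2 * r2 + 3.0 * k3 * r2 * r2
    jxx = radial + 2.0 * x * x * dradial + 2.0 * p1 * y + 6.0 * p2 * x
    jxy = 2.0 * x * y * dradial + 2.0 * p1 * x + 2.0 * p2 * y
    jyx = 2.0 * x * y * dradial + 2.0 * p1 * x + 2.0 * p2 * y
    jyy = radial + 2.0 * y * y * dradial + 6.0 * p1 * y + 2.0 * p2 * x
    return jxx, jxy, jyx, jyy


def _normalized_to_pixel(intrinsics: CameraIntrinsics, xy_distorted) -> np.ndarray:
    x, y = xy_distorted[..., 0], xy_distorted[..., 1]
    u = intrinsics.focal_u * x + intrinsics.skew * y + intrinsics.principal_u
    v = intrinsics.focal_v * y + intrinsics.principal_v
    return np.stack([u, v], axis=-1)


def _pixel_to_distorted_normalized(intrinsics: CameraIntrinsics, pixels) -> np.ndarray:
    pixels = np.asarray(pixels, dtype=float)
    v = (pixels[..., 1] - intrinsics.principal_v) / intrinsics.focal_v
    u = (pixels[..., 0] - intrinsics.principal_u - intrinsics.skew * v) / intrinsics.focal_u
    return np.stack([u, v], axis=-1)


def undistort(
    intrinsics: CameraIntrinsics,
    pixels,
    max_iter: int = 50,
    tol: float = 1e-12,
) -> np.ndarray:
    """Map pixel coordinates to undistorted normalised coordinates.

    Inverts the distortion polynomial by damped Newton iteration on the 2x2
    system; vectorised over any leading shape. Raises :class:`ConvergenceError`
    if any point fails to converge within ``max_iter`` iterations.
    """
    pixels = np.asarray(pixels, dtype=float)
    target = _pixel_to_distorted_normalized(intrinsics, pixels)
    if not np.any(intrinsics.distortion):
        return target
    xy = target.copy()
    for _ in range(max_iter):
        res = distort_normalized(intrinsics, xy) - target
        if np.max(np.abs(res)) < tol:
            break
        x, y = xy[..., 0], xy[..., 1]
        jxx, jxy, jyx, jyy = _distortion_jacobian(intrinsics, x, y)
        det = jxx * jyy - jxy * jyx
        det = np.where(np.abs(det) < 1e-14, np.sign(det) * 1e-14 + (det == 0) * 1e-14, det)
        dx = (jyy * res[..., 0] - jxy * res[..., 1]) / det
        dy = (-jyx * res[..., 0] + jxx * res[..., 1]) / det
        xy = xy - np.stack([dx, dy], axis=-1)
    else:
        raise ConvergenceError("undistortion did not converge")
    return xy


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def project(camera: Camera, points_world) -> np.ndarray:
    """Project world points (mm) to pixel coordinates; shape ``(..., 3) -> (..., 2)``.

    Raises :class:`BehindCameraError` if any point has non-positive depth.
    """
    uv, in_front = project_safe(camera, points_world)
    if not np.all(in_front):
        raise BehindCameraError(
            f"point(s) behind camera {camera.camera_id} (z_cam <= 0)"
        )
    return uv


def project_safe(camera: Camera, points_world) -> tuple[np.ndarray, np.ndarray]:
    """Like :func:`project` but returns ``(uv, in_front_mask)``; points behind
    the camera yield NaN pixels instead of raising."""
    pts = np.asarray(points_world, dtype=float)
    Xc = pts @ camera.pose.rotation.T + camera.pose.translation
    z = Xc[..., 2]
    in_front = z > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        xy = Xc[..., :2] / z[..., None]
    xy = np.where(in_front[..., None], xy, np.nan)
    uv = _normalized_to_pixel(camera.intrinsics, distort_normalized(camera.intrinsics, xy))
    return uv, in_front


# ---------------------------------------------------------------------------
# triangulation
# ---------------------------------------------------------------------------

def _reprojection_rms(cameras: Sequence[Camera], observations: np.ndarray, X: np.ndarray) -> float:
    d2 = []
    for cam, obs in zip(cameras, observations):
        uv, in_front = project_safe(cam, X)
        if not in_front:
            return float("inf")
        d2.append(float(np.sum((uv - obs) ** 2)))
    return float(np.sqrt(np.mean(d2)))


def _point_residual_jacobian(cameras, observations, X):
    m = len(cameras)
    r = np.empty(2 * m)
    J = np.empty((2 * m, 3))
    for i, (cam, obs) in enumerate(zip(cameras, observations)):
        R, t = cam.pose.rotation, cam.pose.translation
        Xc = R @ X + t
        z = Xc[2]
        if z <= 0:
            return None, None
        x, y = Xc[0] / z, Xc[1] / z
        # d(x, y)/dX_world = [[1/z, 0, -x/z], [0, 1/z, -y/z]] @ R
        A = np.array([[1.0 / z, 0.0, -x / z], [0.0, 1.0 / z, -y / z]]) @ R
        jxx, jxy, jyx, jyy = _distortion_jacobian(cam.intrinsics, x, y)
        D = np.array([[jxx, jxy], [jyx, jyy]])
        K2 = np.array(
            [[cam.intrinsics.focal_u, cam.intrinsics.skew], [0.0, cam.intrinsics.focal_v]]
        )
        xd = distort_normalized(cam.intrinsics, np.array([x, y]))
        uv = _normalized_to_pixel(cam.intrinsics, xd)
        r[2 * i : 2 * i + 2] = uv - obs
        J[2 * i : 2 * i + 2] = K2 @ D @ A
    return r, J


def _refine_point(cameras, observations, X0, max_iter=20, tol=1e-14):
    """Gauss-Newton polish of a triangulated point on pixel reprojection error.

    Keeps the best iterate, so the returned point never has larger total
    squared reprojection error than the input."""
    X = X0.copy()
    best_X = X0.copy()
    r, J = _point_residual_jacobian(cameras, observations, X)
    if r is None:
        return best_X
    best_cost = float(r @ r)
    for _ in range(max_iter):
        prev_cost = best_cost
        step, *_ = np.linalg.lstsq(J, -r, rcond=None)
        # backtracking line search: accept only strict improvement
        scale = 1.0
        improved = False
        for _ in range(12):
            X_try = X + scale * step
            r_try, J_try = _point_residual_jacobian(cameras, observations, X_try)
            if r_try is not None:
                cost = float(r_try @ r_try)
                if cost < best_cost:
                    X, r, J = X_try, r_try, J_try
                    best_cost, best_X = cost, X_try
                    improved = True
                    break
            scale *= 0.5
        if not improved or np.linalg.norm(scale * step) < tol:
            break
        if prev_cost - best_cost <= 1e-12 * (prev_cost + 1e-12):
            break
    return best_X


def _triangulate_normalized(cameras, normalized) -> np.ndarray:
    """Homogeneous linear DLT on undistorted normalised coordinates."""
    rows = []
    for cam, (x, y) in zip(cameras, normalized):
        P = np.hstack([cam.pose.rotation, cam.pose.translation[:, None]])
        rows.append(x * P[2] - P[0])
        rows.append(y * P[2] - P[1])
    A = np.array(rows)
    _, _, Vt = np.linalg.svd(A)
    h = Vt[-1]
    if abs(h[3]) < 1e-10 * np.linalg.norm(h[:3]):
        raise DegenerateGeometryError("rays are parallel; point at infinity")
    return h[:3] / h[3]


def triangulate(
    cameras: Sequence[Camera],
    observations,
    refine: bool = True,
) -> Point3DEstimate:
    """Triangulate one world point from pixel observations in >= 2 cameras.

    Linear DLT on undistorted normalised coordinates, followed (by default) by
    Gauss-Newton refinement of the pixel reprojection error. Fewer than two
    observations yield ``valid=False`` rather than an exception; genuinely
    degenerate geometry (coincident centres, parallel rays) raises
    :class:`DegenerateGeometryError`.
    """
    observations = np.asarray(observations, dtype=float).reshape(-1, 2)
    if len(cameras) != len(observations):
        raise ValueError("one observation per camera required")
    if len(cameras) < 2:
        return Point3DEstimate(np.full(3, np.nan), len(cameras), float("nan"), False)
    centers = np.array([c.pose.camera_center for c in cameras])
    spread = max(
        np.linalg.norm(centers[i] - centers[j])
        for i in range(len(centers))
        for j in range(i + 1, len(centers))
    )
    if spread < 1e-10:
        raise DegenerateGeometryError("all camera centres coincide")
    normalized = [undistort(c.intrinsics, o) for c, o in zip(cameras, observations)]
    X = _triangulate_normalized(cameras, normalized)
    if refine:
        X = _refine_point(cameras, observations, X)
    rms = _reprojection_rms(cameras, observations, X)
    return Point3DEstimate(X, len(cameras), rms, True)


def triangulate_series(
    rig: RigCalibration,
    detections: DetectionSet,
    subset: Sequence[str] | None = None,
    min_views: int = 2,
    confidence_threshold: float = 0.5,
    refine: bool = True,
) -> Pose3DSeries:
    """Triangulate every (frame, keypoint) of a detection set using a camera subset.

    Only detections from ``subset`` cameras with ``confidence >=
    confidence_threshold`` and not flagged missing contribute. Entries seen by
    fewer than ``min_views`` cameras are marked invalid, not raised.
    """
    if subset is None:
        subset = rig.camera_ids
    cams = {c.camera_id: c for c in rig.subset(subset)}
    tab = detections.table
    usable = tab[
        tab["camera_id"].isin(cams)
        & ~tab["missing"]
        & (tab["confidence"] >= confidence_threshold)
    ]
    frames = detections.frames
    keypoints = detections.keypoints

    # pre-undistort per camera (vectorised Newton) once
    norm_by_cam = {}
    for cid, sub in usable.groupby("camera_id"):
        px = sub[["u", "v"]].to_numpy()
        norm_by_cam[cid] = dict(zip(sub.index, undistort(cams[cid].intrinsics, px)))

    groups: dict[tuple, list] = {}
    for idx, row in usable.iterrows():
        groups.setdefault((row["frame"], row["keypoint"]), []).append(
            (row["camera_id"], idx, row["u"], row["v"])
        )

    records = []
    for f in frames:
        for kp in keypoints:
            members = groups.get((f, kp), [])
            if len(members) < max(min_views, 2):
                records.append((f, kp, np.nan, np.nan, np.nan, len(members), np.nan, False))
                continue
            cam_list = [cams[cid] for cid, _, _, _ in members]
            obs = np.array([[u, v] for _, _, u, v in members])
            normalized = [norm_by_cam[cid][idx] for cid, idx, _, _ in members]
            try:
                X = _triangulate_normalized(cam_list, normalized)
            except DegenerateGeometryError:
                records.append((f, kp, np.nan, np.nan, np.nan, len(members), np.nan, False))
                continue
            if refine:
                X = _refine_point(cam_list, obs, X)
            rms = _reprojection_rms(cam_list, obs, X)
            records.append((f, kp, X[0], X[1], X[2], len(members), rms, True))
    import pandas as pd

    return Pose3DSeries(
        pd.DataFrame(
            records,
            columns=[
                "frame",
                "keypoint",
                "x",
                "y",
                "z",
                "n_cameras_used",
                "reprojection_rms",
                "valid",
            ],
        )
    )


# ---------------------------------------------------------------------------
# resectioning and rig refinement
# ---------------------------------------------------------------------------

def _check_noncoplanar(points3d: np.ndarray):
    centered = points3d - points3d.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[2] <= 1e-8 * max(s[0], 1.0):
        raise DegenerateGeometryError("correspondences are (near-)coplanar")


def _dlt_projection_matrix(points3d: np.ndarray, pix: np.ndarray) -> np.ndarray:
    n = len(points3d)
    A = np.zeros((2 * n, 12))
    Xh = np.hstack([points3d, np.ones((n, 1))])
    A[0::2, 0:4] = Xh
    A[0::2, 8:12] = -pix[:, 0:1] * Xh
    A[1::2, 4:8] = Xh
    A[1::2, 8:12] = -pix[:, 1:2] * Xh
    _, _, Vt = np.linalg.svd(A)
    return Vt[-1].reshape(3, 4)


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])


def _pose_cost(points3d, pixels, intrinsics, R, t):
    cam = Camera("_", intrinsics, CameraPose(R, t))
    uv, in_front = project_safe(cam, points3d)
    if not np.all(in_front):
        return float("inf"), None
    res = (uv - pixels).ravel()
    return float(res @ res), res


def _refine_pose(points3d, pixels, intrinsics, R0, t0, max_iter=60, tol=1e-14):
    """Gauss-Newton pose-only refinement (6 dof) on pixel reprojection error."""
    R, t = R0.copy(), t0.copy()
    cost, _ = _pose_cost(points3d, pixels, intrinsics, R, t)
    for _ in range(max_iter):
        Xc = points3d @ R.T + t
        z = Xc[:, 2]
        if np.any(z <= 0):
            break
        x, y = Xc[:, 0] / z, Xc[:, 1] / z
        jxx, jxy, jyx, jyy = _distortion_jacobian(intrinsics, x, y)
        fu, fv, sk = intrinsics.focal_u, intrinsics.focal_v, intrinsics.skew
        n = len(points3d)
        r = np.empty(2 * n)
        J = np.empty((2 * n, 6))
        uv = _normalized_to_pixel(
            intrinsics, distort_normalized(intrinsics, np.stack([x, y], axis=-1))
        )
        r[0::2] = uv[:, 0] - pixels[:, 0]
        r[1::2] = uv[:, 1] - pixels[:, 1]
        for i in range(n):
            A = np.array(
                [[1.0 / z[i], 0.0, -x[i] / z[i]], [0.0, 1.0 / z[i], -y[i] / z[i]]]
            )
            D = np.array([[jxx[i], jxy[i]], [jyx[i], jyy[i]]])
            K2 = np.array([[fu, sk], [0.0, fv]])
            B = K2 @ D @ A  # dpx/dXc
            # left-multiplicative increment: Xc' = exp([d_rot]x) R X + t + d_t
            J[2 * i : 2 * i + 2, :3] = B @ (-_skew(R @ points3d[i]))
            J[2 * i : 2 * i + 2, 3:] = B
        step, *_ = np.linalg.lstsq(J, -r, rcond=None)
        scale, improved = 1.0, False
        for _ in range(15):
            dR = Rotation.from_rotvec(scale * step[:3]).as_matrix()
            R_try, t_try = dR @ R, t + scale * step[3:]
            c_try, _ = _pose_cost(points3d, pixels, intrinsics, R_try, t_try)
            if c_try < cost:
                R, t, cost = R_try, t_try, c_try
                improved = True
                break
            scale *= 0.5
        if not improved or np.linalg.norm(scale * step) < tol:
            break
    # re-orthonormalise against drift
    U, _, Vt = np.linalg.svd(R)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        R = -R
    return R, t, cost


def resect(
    correspondences: Sequence[tuple],
    intrinsics_known: CameraIntrinsics | None = None,
    camera_id: str = "camera",
) -> tuple[Camera, float]:
    """Recover a camera from 3D-2D correspondences (DLT + decomposition).

    ``correspondences`` is a sequence of ``(point3d_mm, (u, v))`` pairs. With
    ``intrinsics_known`` the pose alone is estimated (pixels are undistorted
    first, then pose-only Gauss-Newton refinement); otherwise the full
    projection matrix is estimated and RQ-decomposed, with distortion assumed
    zero. Returns ``(camera, reprojection_rms_px)``.
    """
    pts = np.array([np.asarray(p, dtype=float).reshape(3) for p, _ in correspondences])
    pix = np.array([np.asarray(q, dtype=float).reshape(2) for _, q in correspondences])
    if len(pts) < 6:
        raise ValueError("resectioning needs at least 6 correspondences")
    _check_noncoplanar(pts)

    if intrinsics_known is not None:
        norm = undistort(intrinsics_known, pix)
        P = _dlt_projection_matrix(pts, norm)
        M = P[:, :3]
        if np.linalg.det(M) < 0:
            P, M = -P, -M
        P = P / np.linalg.norm(M[2])
        M = P[:, :3]
        U, _, Vt = np.linalg.svd(M)
        R = U @ Vt
        if np.linalg.det(R) < 0:
            R = -R
        t = P[:, 3]
        if np.mean(pts @ R.T + t, axis=0)[2] < 0:
            R, t = -R, -t
            U, _, Vt = np.linalg.svd(-M)
            R = U @ Vt
            if np.linalg.det(R) < 0:
                R = -R
        R, t, _ = _refine_pose(pts, pix, intrinsics_known, R, t)
        cam = Camera(camera_id, intrinsics_known, CameraPose(R, t))
    else:
        P = _dlt_projection_matrix(pts, pix)
        M = P[:, :3]
        if np.linalg.det(M) < 0:
            P, M = -P, -M
        K, R = scipy.linalg.rq(M)
        D = np.diag(np.sign(np.diag(K)))
        K, R = K @ D, D @ R
        t = np.linalg.solve(K, P[:, 3])
        K = K / K[2, 2]
        w = max(int(np.ceil(2 * K[0, 2])), int(np.ceil(pix[:, 0].max())) + 1, 1)
        h = max(int(np.ceil(2 * K[1, 2])), int(np.ceil(pix[:, 1].max())) + 1, 1)
        intr = CameraIntrinsics(
            K[0, 0], K[1, 1], K[0, 2], K[1, 2], skew=K[0, 1],
            image_width=w, image_height=h,
        )
        cam = Camera(camera_id, intr, CameraPose(R, t))
    uv = project(cam, pts)
    rms = float(np.sqrt(np.mean(np.sum((uv - pix) ** 2, axis=1))))
    return cam, rms


@dataclass
class RigRefinementReport:
    """Bookkeeping from :func:`refine_rig`."""

    initial_rms: float
    final_rms: float
    warning: bool


def refine_rig(
    rig: RigCalibration,
    correspondences: Mapping[str, tuple],
) -> tuple[RigCalibration, RigRefinementReport]:
    """Polish every camera pose against its own 3D-2D correspondences.

    ``correspondences`` maps camera_id to ``(points3d (n,3), pixels (n,2))``
    with n >= 6 per camera. Intrinsics are held fixed. The total squared
    reprojection error is guaranteed non-increasing: a camera whose refinement
    step diverges keeps its initial pose and sets the warning flag.
    """
    new_cams = []
    tot0 = tot1 = 0.0
    n_obs = 0
    warning = False
    for cam in rig.cameras:
        if cam.camera_id not in correspondences:
            raise ConfigurationError(f"no correspondences for {cam.camera_id}")
        pts, pix = correspondences[cam.camera_id]
        pts = np.asarray(pts, dtype=float).reshape(-1, 3)
        pix = np.asarray(pix, dtype=float).reshape(-1, 2)
        if len(pts) < 6:
            raise ValueError(f"camera {cam.camera_id}: need >= 6 correspondences")
        c0, _ = _pose_cost(pts, pix, cam.intrinsics, cam.pose.rotation, cam.pose.translation)
        R, t, c1 = _refine_pose(pts, pix, cam.intrinsics, cam.pose.rotation.copy(),
                                cam.pose.translation.copy())
        if not np.isfinite(c1) or c1 > c0:
            R, t, c1 = cam.pose.rotation, cam.pose.translation, c0
            warning = True
        new_cams.append(Camera(cam.camera_id, cam.intrinsics, CameraPose(R, t)))
        tot0 += c0
        tot1 += c1
        n_obs += len(pts)
    report = RigRefinementReport(
        initial_rms=float(np.sqrt(tot0 / n_obs)),
        final_rms=float(np.sqrt(tot1 / n_obs)),
        warning=warning,
    )
    return RigCalibration(new_cams, units_note=rig.units_note), report
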