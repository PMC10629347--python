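"""Synthetic capture-arena simulator.

Emulates a surround-view rodent arena: three side cameras spaced at 120 deg
on a horizontal ring plus one camera below a transparent floor, all aimed at
the capture volume. A rigid test object follows a smooth seeded trajectory;
its keypoints are projected into every camera and corrupted with Gaussian
pixel noise, optional outliers, and stochastic detection dropout, which
stands in for occlusion (geometric self-occlusion is deliberately not
modelled). A single global seed is expanded into independent per-stage
streams so trajectory, noise and dropout can be varied independently.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .cameras import Camera, CameraIntrinsics, CameraPose, RigCalibration, project_safe
from .detections import DetectionSet
from .testobject import RigidPose, TestObjectSpec, make_xyz_object, place_object

__all__ = [
    "NoiseModel",
    "RigLayout",
    "SimulationBundle",
    "TrajectoryConfig",
    "build_rig",
    "default_intrinsics",
    "mouse_like_preset",
    "render_detections",
    "simulate_bundle",
    "simulate_trajectory",
]

#: sensor defaults: 1280x800 global-shutter sensor behind a 2.4 mm lens.
#: The pixel pitch is not a published figure; 3 um is assumed and exposed,
#: giving a focal length of 800 px. Only relative geometry matters here.
SENSOR_WIDTH = 1280
SENSOR_HEIGHT = 800
FOCAL_LENGTH_MM = 2.4
PIXEL_PITCH_MM = 0.003


def default_intrinsics(
    image_width: int = SENSOR_WIDTH,
    image_height: int = SENSOR_HEIGHT,
    focal_mm: float = FOCAL_LENGTH_MM,
    pixel_pitch_mm: float = PIXEL_PITCH_MM,
    distortion=(0.0, 0.0, 0.0, 0.0, 0.0),
) -> CameraIntrinsics:
    f_px = focal_mm / pixel_pitch_mm
    return CameraIntrinsics(
        focal_u=f_px,
        focal_v=f_px,
        principal_u=image_width / 2.0,
        principal_v=image_height / 2.0,
        distortion=np.asarray(distortion, dtype=float),
        image_width=image_width,
        image_height=image_height,
    )


@dataclass
class RigLayout:
    """Geometric description of the camera ring plus bottom camera.

    ``camera_distance`` is the ring radius from the arena centre (mm);
    ``side_elevation`` the ring height above the floor; ``bottom_depth`` how
    far below the floor the upward-looking camera sits.
    """

    n_side_cameras: int = 3
    camera_distance: float = 150.0
    side_elevation: float = 30.0
    bottom_depth: float = 120.0
    intrinsics_template: CameraIntrinsics = field(default_factory=default_intrinsics)
    look_at: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 30.0]))

    def __post_init__(self):
        if self.n_side_cameras < 1:
            raise ValueError("need at least one side camera")
        if self.camera_distance <= 0:
            raise ValueError("camera_distance must be positive")
        self.look_at = np.asarray(self.look_at, dtype=float).reshape(3)

    @classmethod
    def small_arena(cls, **kw) -> "RigLayout":
        """89 mm cylinder arena; ring radius 150 mm (chosen, not published)."""
        return cls(camera_distance=150.0, **kw)

    @classmethod
    def large_arena(cls, **kw) -> "RigLayout":
        """320 mm plate arena with cameras 340 mm from the centre."""
        return cls(camera_distance=340.0, **kw)


@dataclass
class TrajectoryConfig:
    """Smooth seeded rigid trajectory parameters.

    ``rotation_rate`` is degrees per frame about a slowly precessing axis;
    ``translation_amplitude`` bounds the smooth random excursion (mm) around
    ``center``. Defaults give the slow, smooth presentation appropriate for a
    hand-held test object filmed at 30 fps.
    """

    n_frames: int = 200
    frame_rate: float = 30.0
    rotation_rate: float = 1.0
    translation_amplitude: float = 10.0
    seed: int = 0
    center: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 30.0]))

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        self.center = np.asarray(self.center, dtype=float).reshape(3)


@dataclass
class NoiseModel:
    """Statistical corruption applied to rendered 2D detections.

    ``p_miss`` is the baseline per-(camera, keypoint, frame) dropout
    probability — the occlusion proxy. ``p_miss_by_camera`` overrides it per
    camera; ``p_miss_by_camera_keypoint`` (keys ``(camera_id, keypoint)``)
    overrides both, which is how view-dependent visibility (e.g. ventral
    keypoints hidden from side views) is expressed. ``confidence_law`` is
    either ``"binary"`` (1 for rendered, 0 for missing) or ``"noise_scaled"``
    (confidence shrinks with the drawn pixel perturbation — useful for
    exercising confidence thresholds).
    """

    pixel_sigma: float = 0.0
    p_miss: float = 0.0
    p_miss_by_camera: dict[str, float] | None = None
    p_miss_by_camera_keypoint: dict[tuple[str, str], float] | None = None
    outlier_prob: float = 0.0
    outlier_sigma: float = 20.0
    confidence_law: str = "binary"

    def __post_init__(self):
        if self.pixel_sigma < 0 or self.outlier_sigma < 0:
            raise ValueError("sigmas must be non-negative")
        for p in [self.p_miss, self.outlier_prob] + list(
            (self.p_miss_by_camera or {}).values()
        ) + list((self.p_miss_by_camera_keypoint or {}).values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.confidence_law not in ("binary", "noise_scaled"):
            raise ValueError("confidence_law must be 'binary' or 'noise_scaled'")

    def miss_probability(self, camera_id: str, keypoint: str) -> float:
        if self.p_miss_by_camera_keypoint is not None:
            key = (camera_id, keypoint)
            if key in self.p_miss_by_camera_keypoint:
                return self.p_miss_by_camera_keypoint[key]
        if self.p_miss_by_camera is not None and camera_id in self.p_miss_by_camera:
            return self.p_miss_by_camera[camera_id]
        return self.p_miss

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.p_miss_by_camera_keypoint is not None:
            d["p_miss_by_camera_keypoint"] = {
                f"{c}|{k}": v for (c, k), v in self.p_miss_by_camera_keypoint.items()
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseModel":
        d = dict(d)
        pk = d.get("p_miss_by_camera_keypoint")
        if pk is not None:
            d["p_miss_by_camera_keypoint"] = {
                tuple(k.split("|", 1)): v for k, v in pk.items()
            }
        return cls(**d)


@dataclass
class SimulationBundle:
    """Everything one simulated session produces, plus its configuration echo."""

    rig: RigCalibration
    detections: DetectionSet
    truth_3d: pd.DataFrame  # long form: frame, keypoint, x, y, z (mm)
    poses: list[RigidPose]
    object_spec: TestObjectSpec
    seed: int
    config: dict


# ---------------------------------------------------------------------------
# rig construction
# ---------------------------------------------------------------------------

def _look_at_pose(center: np.ndarray, target: np.ndarray) -> CameraPose:
    """World-to-camera pose for a camera at ``center`` aimed at ``target``,
    kept upright (world +z maps toward image up) where possible."""
    z = target - center
    nz = np.linalg.norm(z)
    if nz < 1e-9:
        raise ValueError("camera centre coincides with its look-at target")
    z = z / nz
    hint = np.array([0.0, 0.0, 1.0])
    if abs(z @ hint) > 0.99:
        hint = np.array([1.0, 0.0, 0.0])
    x = np.cross(z, hint)
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    R = np.vstack([x, y, z])
    return CameraPose(R, -R @ center)


def build_rig(layout: RigLayout) -> RigCalibration:
    """Place ``n_side_cameras`` at equal azimuth spacing on the ring plus one
    bottom camera at ``(0, 0, -bottom_depth)``, all aimed at ``look_at``.

    Camera ids are ``cam_0 .. cam_{n-1}`` for the sides and ``cam_{n}`` for
    the bottom camera (last in the rig).
    """
    cams = []
    for i in range(layout.n_side_cameras):
        az = 2.0 * np.pi * i / layout.n_side_cameras
        center = np.array(
            [
                layout.camera_distance * np.cos(az),
                layout.camera_distance * np.sin(az),
                layout.side_elevation,
            ]
        )
        cams.append(
            Camera(f"cam_{i}", layout.intrinsics_template, _look_at_pose(center, layout.look_at))
        )
    bottom_center = np.array([0.0, 0.0, -layout.bottom_depth])
    cams.append(
        Camera(
            f"cam_{layout.n_side_cameras}",
            layout.intrinsics_template,
            _look_at_pose(bottom_center, layout.look_at),
        )
    )
    return RigCalibration(cams)


def bottom_camera_id(rig: RigCalibration) -> str:
    """By construction the bottom camera is the last camera of a built rig."""
    return rig.cameras[-1].camera_id


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------

def _smooth_signals(rng: np.random.Generator, n_frames: int, frame_rate: float,
                    n_channels: int, n_harmonics: int = 3,
                    freq_range=(0.05, 0.4)) -> np.ndarray:
    """Band-limited unit-amplitude signals: sums of random-phase sinusoids,
    normalised so each channel stays within [-1, 1]."""
    t = np.arange(n_frames) / frame_rate
    out = np.zeros((n_channels, n_frames))
    for c in range(n_channels):
        freqs = rng.uniform(*freq_range, size=n_harmonics)
        phases = rng.uniform(0, 2 * np.pi, size=n_harmonics)
        amps = rng.uniform(0.3, 1.0, size=n_harmonics)
        s = np.sum(
            amps[:, None] * np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]),
            axis=0,
        )
        peak = np.max(np.abs(s))
        out[c] = s / peak if peak > 0 else s
    return out


def simulate_trajectory(spec: TestObjectSpec, config: TrajectoryConfig) -> list[RigidPose]:
    """Smooth seeded rigid trajectory: incremental rotation at
    ``rotation_rate`` deg/frame about a slowly precessing axis, translation a
    bounded band-limited excursion around ``config.center``. Identical seeds
    yield bitwise-identical pose lists."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n_frames
    R = Rotation.random(random_state=np.random.RandomState(
        int(rng.integers(0, 2**31 - 1)))).as_matrix()
    trans_sig = _smooth_signals(rng, n, config.frame_rate, 3)
    axis_sig = _smooth_signals(rng, n, config.frame_rate, 2, freq_range=(0.02, 0.1))
    az0, el0 = rng.uniform(0, 2 * np.pi), rng.uniform(-0.5, 0.5)

    poses = []
    step_rad = np.deg2rad(config.rotation_rate)
    for i in range(n):
        t = config.center + config.translation_amplitude * trans_sig[:, i]
        poses.append(RigidPose(R.copy(), t))
        az = az0 + 0.6 * axis_sig[0, i]
        el = el0 + 0.6 * axis_sig[1, i]
        axis = np.array([np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)])
        R = Rotation.from_rotvec(step_rad * axis).as_matrix() @ R
    return poses


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_detections(
    rig: RigCalibration,
    spec: TestObjectSpec,
    poses: list[RigidPose],
    noise: NoiseModel,
    seed: int,
) -> DetectionSet:
    """Project the posed object into every camera and corrupt the result.

    Per (frame, camera, keypoint): the point is missing if it lies behind the
    camera, projects outside the image bounds, or is dropped by the
    per-record dropout draw; otherwise isotropic Gaussian pixel noise (or,
    with ``outlier_prob``, wide outlier noise) is added and a confidence is
    assigned by the configured law. Fully reproducible from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    rng_drop, rng_noise, rng_outlier = (np.random.default_rng(s) for s in ss.spawn(3))

    kp_names = spec.keypoint_names
    world = np.array([[place_object(spec, p)[k] for k in kp_names] for p in poses])
    n_frames, n_kp = world.shape[:2]

    records = []
    for cam in rig.cameras:
        uv, in_front = project_safe(cam, world.reshape(-1, 3))
        uv = uv.reshape(n_frames, n_kp, 2)
        in_front = in_front.reshape(n_frames, n_kp)
        w, h = cam.intrinsics.image_width, cam.intrinsics.image_height
        with np.errstate(invalid="ignore"):
            in_bounds = (
                (uv[..., 0] >= 0) & (uv[..., 0] <= w) & (uv[..., 1] >= 0) & (uv[..., 1] <= h)
            )
        p_miss = np.array([noise.miss_probability(cam.camera_id, k) for k in kp_names])
        dropped = rng_drop.random((n_frames, n_kp)) < p_miss[None, :]
        missing = ~in_front | ~in_bounds | dropped

        gauss = rng_noise.normal(0.0, 1.0, (n_frames, n_kp, 2))
        is_outlier = rng_outlier.random((n_frames, n_kp)) < noise.outlier_prob
        sigma = np.where(is_outlier, noise.outlier_sigma, noise.pixel_sigma)
        perturb = gauss * sigma[..., None]
        uv_noisy = uv + perturb

        if noise.confidence_law == "binary":
            conf = np.ones((n_frames, n_kp))
        else:
            mag = np.linalg.norm(perturb, axis=-1)
            conf = 1.0 / (1.0 + (mag / 2.0) ** 2)
        conf = np.where(missing, 0.0, conf)

        for f in range(n_frames):
            for k in range(n_kp):
                m = bool(missing[f, k])
                records.append(
                    (
                        f,
                        cam.camera_id,
                        kp_names[k],
                        np.nan if m else float(uv_noisy[f, k, 0]),
                        np.nan if m else float(uv_noisy[f, k, 1]),
                        float(conf[f, k]),
                        m,
                    )
                )
    return DetectionSet(
        pd.DataFrame(
            records,
            columns=["frame", "camera_id", "keypoint", "u", "v", "confidence", "missing"],
        )
    )


def simulate_bundle(
    layout: RigLayout | None = None,
    spec: TestObjectSpec | None = None,
    trajectory: TrajectoryConfig | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> SimulationBundle:
    """Run the full simulator: build the rig, draw a trajectory, render noisy
    detections, and keep the ground-truth 3D series alongside."""
    layout = layout or RigLayout.small_arena()
    spec = spec or make_xyz_object()
    ss = np.random.SeedSequence(seed)
    traj_seed, render_seed = (int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2))
    trajectory = trajectory or TrajectoryConfig()
    trajectory = TrajectoryConfig(
        n_frames=trajectory.n_frames,
        frame_rate=trajectory.frame_rate,
        rotation_rate=trajectory.rotation_rate,
        translation_amplitude=trajectory.translation_amplitude,
        seed=traj_seed,
        center=trajectory.center,
    )
    noise = noise or NoiseModel()
    rig = build_rig(layout)
    poses = simulate_trajectory(spec, trajectory)
    detections = render_detections(rig, spec, poses, noise, seed=render_seed)
    truth_rows = []
    for f, pose in enumerate(poses):
        placed = place_object(spec, pose)
        for k, p in placed.items():
            truth_rows.append((f, k, p[0], p[1], p[2]))
    truth = pd.DataFrame(truth_rows, columns=["frame", "keypoint", "x", "y", "z"])
    config = {
        "layout": {
            "n_side_cameras": layout.n_side_cameras,
            "camera_distance": layout.camera_distance,
            "side_elevation": layout.side_elevation,
            "bottom_depth": layout.bottom_depth,
        },
        "trajectory": {
            "n_frames": trajectory.n_frames,
            "frame_rate": trajectory.frame_rate,
            "rotation_rate": trajectory.rotation_rate,
            "translation_amplitude": trajectory.translation_amplitude,
        },
        "noise": noise.to_dict(),
        "seed": seed,
    }
    return SimulationBundle(rig, detections, truth, poses, spec, seed, config)


# ---------------------------------------------------------------------------
# mouse-like preset
# ---------------------------------------------------------------------------

def mouse_like_preset() -> tuple[TestObjectSpec, NoiseModel]:
    """Rigid stand-in for a mouse with view-dependent keypoint visibility.

    The "skeleton" is a rigid 9-keypoint body plan (snout, ears, spine, tail
    base, four paws) at roughly adult-mouse scale. Ventral keypoints (the
    paws) are far more likely to drop out of the three side views than the
    bottom view, reproducing the visibility asymmetry of a floor-walking
    animal. Camera ids follow :func:`build_rig` with three side cameras
    (``cam_0..cam_2``) and bottom camera ``cam_3``.
    """
    kp = {
        "snout": [35.0, 0.0, 8.0],
        "left_ear": [25.0, 8.0, 12.0],
        "right_ear": [25.0, -8.0, 12.0],
        "spine_mid": [0.0, 0.0, 15.0],
        "tail_base": [-35.0, 0.0, 10.0],
        "paw_front_left": [20.0, 10.0, 1.0],
        "paw_front_right": [20.0, -10.0, 1.0],
        "paw_hind_left": [-20.0, 12.0, 1.0],
        "paw_hind_right": [-20.0, -12.0, 1.0],
    }
    spec = TestObjectSpec(name="mouse-like-rigid", keypoints=kp)
    ventral = [k for k in kp if k.startswith("paw_")]
    side_cams = ["cam_0", "cam_1", "cam_2"]
    overrides = {(c, k): 0.6 for c, k in itertools.product(side_cams, ventral)}
    noise = NoiseModel(
        pixel_sigma=1.0,
        p_miss=0.1,
        p_miss_by_camera={"cam_3": 0.05},
        p_miss_by_camera_keypoint=overrides,
    )
    return spec, noise
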