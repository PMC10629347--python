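"""File formats: detection CSVs, calibration TOML, 3D series CSV, run config.

Dialects
--------
* Detections: the three-header-row CSV layout used by markerless-tracking
  toolchains (``scorer`` / ``bodyparts`` / ``coords`` rows; per keypoint an
  x, y, likelihood column triple; one data row per 0-based frame).
* Calibration: TOML with one ``[cam_i]`` section per camera holding ``name``,
  ``size`` (w, h), ``matrix`` (3x3 row-major), ``distortions`` (5-vector),
  ``rotation`` (Rodrigues 3-vector) and ``translation`` (mm). The reader
  tolerates extra keys; the writer emits exactly these.
* 3D series: wide CSV, one row per frame with per-keypoint x/y/z/error/ncams.

Units are fixed: mm in 3D files, px in 2D files; no autodetection.
"""

from __future__ import annotations

import tomllib
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .cameras import Camera, CameraIntrinsics, CameraPose, RigCalibration
from .detections import DetectionSet, Pose3DSeries

__all__ = [
    "RunConfig",
    "read_calibration_toml",
    "read_dlc_csv",
    "read_pose3d_csv",
    "write_calibration_toml",
    "write_dlc_csv",
    "write_pose3d_csv",
]


# ---------------------------------------------------------------------------
# detection CSVs
# ---------------------------------------------------------------------------

def write_dlc_csv(
    detections: DetectionSet,
    path,
    camera_id: str,
    scorer: str = "rigval",
) -> None:
    """Write one camera's detections in the three-header-row CSV dialect."""
    tab = detections.table[detections.table["camera_id"] == camera_id]
    if tab.empty:
        raise ValueError(f"no detections for camera {camera_id!r}")
    keypoints = list(dict.fromkeys(tab["keypoint"]))
    frames = np.sort(tab["frame"].unique())
    wide = tab.pivot(index="frame", columns="keypoint", values=["u", "v", "confidence"])
    cols = pd.MultiIndex.from_tuples(
        [(scorer, kp, coord) for kp in keypoints for coord in ("x", "y", "likelihood")],
        names=["scorer", "bodyparts", "coords"],
    )
    out = pd.DataFrame(index=frames, columns=cols, dtype=float)
    for kp in keypoints:
        out[(scorer, kp, "x")] = wide[("u", kp)]
        out[(scorer, kp, "y")] = wide[("v", kp)]
        out[(scorer, kp, "likelihood")] = wide[("confidence", kp)]
    out.to_csv(path)


def read_dlc_csv(path, camera_id: str) -> DetectionSet:
    """Read a three-header-row detection CSV for one camera.

    Column order within each keypoint block follows the ``coords`` header
    labels, so permuted x/y/likelihood columns are handled. Non-finite
    coordinates mark the record missing (likelihood mapped to confidence 0).
    """
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"{path}: malformed detection CSV header: {exc}") from exc
    if df.columns.nlevels != 3:
        raise ValueError(f"{path}: expected 3 header rows (scorer/bodyparts/coords)")
    coords_level = df.columns.get_level_values(2)
    if not {"x", "y", "likelihood"} <= set(coords_level):
        raise ValueError(
            f"{path}: coords header row must contain x, y and likelihood "
            f"(got {sorted(set(coords_level))})"
        )
    keypoints = list(dict.fromkeys(df.columns.get_level_values(1)))
    records = []
    for kp in keypoints:
        block = df.xs(kp, axis=1, level=1)
        block.columns = block.columns.get_level_values(-1)
        for frame, row in block.iterrows():
            u, v, lik = row.get("x"), row.get("y"), row.get("likelihood")
            missing = not (np.isfinite(u) and np.isfinite(v))
            records.append(
                (
                    int(frame),
                    camera_id,
                    kp,
                    float("nan") if missing else float(u),
                    float("nan") if missing else float(v),
                    0.0 if missing or not np.isfinite(lik) else float(lik),
                    missing,
                )
            )
    return DetectionSet(
        pd.DataFrame(
            records,
            columns=["frame", "camera_id", "keypoint", "u", "v", "confidence", "missing"],
        )
    )


# ---------------------------------------------------------------------------
# calibration TOML
# ---------------------------------------------------------------------------

def _toml_value(v) -> str:
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple)):
        return "[ " + ", ".join(_toml_value(x) for x in v) + " ]"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    return repr(float(v))


def write_calibration_toml(rig: RigCalibration, path) -> None:
    """Emit the calibration dialect: sections ``[cam_0] .. [cam_{n-1}]``.

    Rotations are serialised as Rodrigues 3-vectors; matrices row-major."""
    lines = []
    for i, cam in enumerate(rig.cameras):
        intr = cam.intrinsics
        lines.append(f"[cam_{i}]")
        lines.append(f"name = {_toml_value(cam.camera_id)}")
        lines.append(f"size = {_toml_value([intr.image_width, intr.image_height])}")
        lines.append(f"matrix = {_toml_value([list(r) for r in intr.matrix])}")
        lines.append(f"distortions = {_toml_value(list(intr.distortion))}")
        lines.append(f"rotation = {_toml_value(list(cam.pose.as_rotvec()))}")
        lines.append(f"translation = {_toml_value(list(cam.pose.translation))}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_calibration_toml(path) -> RigCalibration:
    """Read the calibration dialect; extra keys in a section are ignored."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    sections = sorted(
        (k for k in data if k.startswith("cam_")), key=lambda k: int(k.split("_")[1])
    )
    cams = []
    for key in sections:
        sec = data[key]
        K = np.asarray(sec["matrix"], dtype=float).reshape(3, 3)
        size = sec["size"]
        intr = CameraIntrinsics(
            focal_u=K[0, 0],
            focal_v=K[1, 1],
            principal_u=K[0, 2],
            principal_v=K[1, 2],
            skew=K[0, 1],
            distortion=np.asarray(sec["distortions"], dtype=float),
            image_width=int(size[0]),
            image_height=int(size[1]),
        )
        pose = CameraPose.from_rotvec(sec["rotation"], sec["translation"])
        cams.append(Camera(str(sec.get("name", key)), intr, pose))
    return RigCalibration(cams)


# ---------------------------------------------------------------------------
# 3D series CSV (wide)
# ---------------------------------------------------------------------------

def write_pose3d_csv(series: Pose3DSeries, path) -> None:
    """Wide CSV: frame, then per keypoint ``{kp}_x,_y,_z,_error,_ncams``.

    Invalid entries are written as NaN coordinates with their view count."""
    keypoints = series.keypoints
    frames = series.frames
    idx = series.table.set_index(["frame", "keypoint"])
    cols: dict[str, list] = {"frame": list(frames)}
    for kp in keypoints:
        sub = idx.xs(kp, level="keypoint").reindex(frames)
        cols[f"{kp}_x"] = sub["x"].tolist()
        cols[f"{kp}_y"] = sub["y"].tolist()
        cols[f"{kp}_z"] = sub["z"].tolist()
        cols[f"{kp}_error"] = sub["reprojection_rms"].tolist()
        cols[f"{kp}_ncams"] = sub["n_cameras_used"].fillna(0).astype(int).tolist()
    pd.DataFrame(cols).to_csv(path, index=False)


def read_pose3d_csv(path) -> Pose3DSeries:
    df = pd.read_csv(path)
    if "frame" not in df.columns:
        raise ValueError(f"{path}: 3D CSV must have a 'frame' column")
    keypoints = [c[:-2] for c in df.columns if c.endswith("_x")]
    records = []
    for _, row in df.iterrows():
        for kp in keypoints:
            x, y, z = row[f"{kp}_x"], row[f"{kp}_y"], row[f"{kp}_z"]
            ncams = int(row[f"{kp}_ncams"])
            valid = bool(np.isfinite(x) and np.isfinite(y) and np.isfinite(z) and ncams >= 2)
            records.append(
                (int(row["frame"]), kp, x, y, z, ncams, row[f"{kp}_error"], valid)
            )
    return Pose3DSeries(
        pd.DataFrame(
            records,
            columns=["frame", "keypoint", "x", "y", "z", "n_cameras_used",
                     "reprojection_rms", "valid"],
        )
    )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

class _LayoutConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_side_cameras: int = 3
    camera_distance: float = 150.0
    side_elevation: float = 30.0
    bottom_depth: float = 120.0
    image_width: int = 1280
    image_height: int = 800
    focal_mm: float = 2.4
    pixel_pitch_mm: float = 0.003
    distortion: list[float] = Field(default_factory=lambda: [0.0] * 5)


class _TrajectoryConfigModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_frames: int = 200
    frame_rate: float = 30.0
    rotation_rate: float = 1.0
    translation_amplitude: float = 10.0


class _NoiseConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    pixel_sigma: float = 0.0
    p_miss: float = 0.0
    p_miss_by_camera: Optional[dict[str, float]] = None
    outlier_prob: float = 0.0
    outlier_sigma: float = 20.0
    confidence_law: Literal["binary", "noise_scaled"] = "binary"


class RunConfig(BaseModel):
    """Schema-validated pipeline configuration; unknown keys are rejected
    with their location by the validator."""

    model_config = ConfigDict(extra="forbid")

    preset: Optional[Literal["small", "large"]] = "small"
    seed: int = 0
    rod_length: float = 40.0
    letter_offset: float = 0.0
    layout: _LayoutConfig = Field(default_factory=_LayoutConfig)
    trajectory: _TrajectoryConfigModel = Field(default_factory=_TrajectoryConfigModel)
    noise: _NoiseConfig = Field(default_factory=_NoiseConfig)
    confidence_threshold: float = 0.5
    min_views: int = 2

    def resolved_layout(self):
        from .simulate import RigLayout, default_intrinsics

        intr = default_intrinsics(
            self.layout.image_width,
            self.layout.image_height,
            self.layout.focal_mm,
            self.layout.pixel_pitch_mm,
            self.layout.distortion,
        )
        kw = dict(
            n_side_cameras=self.layout.n_side_cameras,
            side_elevation=self.layout.side_elevation,
            bottom_depth=self.layout.bottom_depth,
            intrinsics_template=intr,
        )
        if self.preset == "large":
            return RigLayout(camera_distance=340.0, **kw)
        if self.preset == "small":
            return RigLayout(camera_distance=150.0, **kw)
        return RigLayout(camera_distance=self.layout.camera_distance, **kw)

    def resolved_trajectory(self):
        from .simulate import TrajectoryConfig

        return TrajectoryConfig(
            n_frames=self.trajectory.n_frames,
            frame_rate=self.trajectory.frame_rate,
            rotation_rate=self.trajectory.rotation_rate,
            translation_amplitude=self.trajectory.translation_amplitude,
            seed=self.seed,
        )

    def resolved_noise(self):
        from .simulate import NoiseModel

        return NoiseModel(
            pixel_sigma=self.noise.pixel_sigma,
            p_miss=self.noise.p_miss,
            p_miss_by_camera=self.noise.p_miss_by_camera,
            outlier_prob=self.noise.outlier_prob,
            outlier_sigma=self.noise.outlier_sigma,
            confidence_law=self.noise.confidence_law,
        )
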