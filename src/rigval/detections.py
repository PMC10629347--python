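"""Tabular containers shared across the pipeline.

Both containers are thin, validated wrappers around a long-form
:class:`pandas.DataFrame`; downstream code works on ``.table`` directly.
Frames are 0-based integers throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DetectionSet", "Pose3DSeries"]

DETECTION_COLUMNS = ["frame", "camera_id", "keypoint", "u", "v", "confidence", "missing"]
POSE3D_COLUMNS = ["frame", "keypoint", "x", "y", "z", "n_cameras_used",
                  "reprojection_rms", "valid"]


@dataclass
class DetectionSet:
    """Per (frame, camera, keypoint) pixel observations with confidence.

    Missing observations are carried explicitly (``missing=True``); their
    pixel coordinates and confidence are ignored by all consumers, never
    treated as (0, 0).
    """

    table: pd.DataFrame

    def __post_init__(self):
        missing_cols = set(DETECTION_COLUMNS) - set(self.table.columns)
        if missing_cols:
            raise ValueError(f"DetectionSet table lacks columns: {sorted(missing_cols)}")
        self.table = self.table[DETECTION_COLUMNS].reset_index(drop=True)
        self.table["frame"] = self.table["frame"].astype(int)
        self.table["missing"] = self.table["missing"].astype(bool)
        if self.table.duplicated(["frame", "camera_id", "keypoint"]).any():
            raise ValueError("(frame, camera_id, keypoint) must be unique")

    @property
    def frames(self) -> np.ndarray:
        return np.sort(self.table["frame"].unique())

    @property
    def camera_ids(self) -> list[str]:
        return sorted(self.table["camera_id"].unique())

    @property
    def keypoints(self) -> list[str]:
        # preserve first-appearance order
        return list(dict.fromkeys(self.table["keypoint"]))

    def present(self) -> pd.DataFrame:
        """Rows that are actually observed (not missing, finite pixels)."""
        t = self.table
        return t[~t["missing"] & np.isfinite(t["u"]) & np.isfinite(t["v"])]

    @classmethod
    def concat(cls, parts) -> "DetectionSet":
        return cls(pd.concat([p.table for p in parts], ignore_index=True))

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class Pose3DSeries:
    """Per (frame, keypoint) reconstructed 3D point (mm) with provenance.

    ``valid`` implies at least two contributing camera views; invalid rows
    keep NaN coordinates.
    """

    table: pd.DataFrame

    def __post_init__(self):
        missing_cols = set(POSE3D_COLUMNS) - set(self.table.columns)
        if missing_cols:
            raise ValueError(f"Pose3DSeries table lacks columns: {sorted(missing_cols)}")
        self.table = self.table[POSE3D_COLUMNS].reset_index(drop=True)
        self.table["frame"] = self.table["frame"].astype(int)
        self.table["valid"] = self.table["valid"].astype(bool)
        bad = self.table["valid"] & (self.table["n_cameras_used"] < 2)
        if bad.any():
            raise ValueError("valid entries must use >= 2 cameras")

    @property
    def frames(self) -> np.ndarray:
        return np.sort(self.table["frame"].unique())

    @property
    def keypoints(self) -> list[str]:
        return list(dict.fromkeys(self.table["keypoint"]))

    def valid_table(self) -> pd.DataFrame:
        return self.table[self.table["valid"]]

    def coverage_fraction(self) -> float:
        """Fraction of (frame, keypoint) entries with a valid 3D estimate."""
        if len(self.table) == 0:
            return float("nan")
        return float(self.table["valid"].mean())

    def __len__(self) -> int:
        return len(self.table)
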