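"""Rigid 3D test objects of known geometry.

The default object mirrors a printable calibration-check target: three
perpendicular rods meeting at a common origin, one per coordinate axis, each
carrying a distinct letter glyph at its tip so every view is visually unique.
Only the trackable anchor keypoints are modelled, not the letter meshes.
All coordinates are millimetres in an object-fixed frame.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RigidPose",
    "TestObjectSpec",
    "ground_truth_distances",
    "make_xyz_object",
    "place_object",
    "read_object_json",
    "write_object_json",
]


@dataclass(frozen=True)
class RigidPose:
    """Object-to-world rigid transform: ``X_world = rotation @ X_obj + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3).copy()
        t = np.asarray(self.translation, dtype=float).reshape(3).copy()
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise ValueError("rotation must have determinant +1")
        R.setflags(write=False)
        t.setflags(write=False)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidPose":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class TestObjectSpec:
    """Named keypoints of a rigid object (object frame, mm) and the distance
    pairs evaluated against ground truth (default: all unordered pairs)."""

    __test__ = False  # not a pytest class despite the name

    name: str
    keypoints: dict[str, np.ndarray]
    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        if len(self.keypoints) < 3:
            raise ValueError("a test object needs at least 3 keypoints")
        self.keypoints = {
            str(k): np.asarray(v, dtype=float).reshape(3)
            for k, v in self.keypoints.items()
        }
        if not self.pairs:
            self.pairs = list(itertools.combinations(self.keypoints, 2))
        self.pairs = [(str(a), str(b)) for a, b in self.pairs]
        for a, b in self.pairs:
            if a not in self.keypoints or b not in self.keypoints:
                raise ValueError(f"pair ({a}, {b}) names an unknown keypoint")
            if np.linalg.norm(self.keypoints[a] - self.keypoints[b]) <= 0:
                raise ValueError(f"pair ({a}, {b}) has zero ground-truth distance")

    @property
    def keypoint_names(self) -> list[str]:
        return list(self.keypoints)

    def coordinates(self) -> np.ndarray:
        """(K, 3) array in keypoint order."""
        return np.array(list(self.keypoints.values()))

    def pair_distance(self, a: str, b: str) -> float:
        return float(np.linalg.norm(self.keypoints[a] - self.keypoints[b]))


def make_xyz_object(
    rod_length: float = 40.0,
    letter_offset: float = 0.0,
    name: str = "xyz-test-object",
) -> TestObjectSpec:
    """Build the three-perpendicular-rod test object.

    Keypoints: ``origin`` at the rod junction plus one letter anchor per axis
    (``X``, ``Y``, ``Z``) at distance ``rod_length`` along +x, +y, +z. The
    bare anchor set retains the two cyclic axis-permutation symmetries; a
    positive ``letter_offset`` adds a secondary point per letter displaced
    sideways in deliberately non-cyclic directions, which makes the keypoint
    set fully chiral (no nontrivial rotation maps it onto itself) — the
    geometric counterpart of the letters' unique visual cues.
    """
    if rod_length <= 0:
        raise ValueError("rod_length must be positive")
    if letter_offset < 0:
        raise ValueError("letter_offset must be non-negative")
    kp: dict[str, np.ndarray] = {
        "origin": np.zeros(3),
        "X": np.array([rod_length, 0.0, 0.0]),
        "Y": np.array([0.0, rod_length, 0.0]),
        "Z": np.array([0.0, 0.0, rod_length]),
    }
    if letter_offset > 0:
        # offset directions must NOT be a cyclic image of one another, or the
        # 3-fold axis-permutation symmetry of the bare anchors would survive
        kp["X2"] = kp["X"] + np.array([0.0, letter_offset, 0.0])
        kp["Y2"] = kp["Y"] + np.array([letter_offset, 0.0, 0.0])
        kp["Z2"] = kp["Z"] + np.array([0.0, letter_offset, 0.0])
    return TestObjectSpec(name=name, keypoints=kp)


def ground_truth_distances(spec: TestObjectSpec) -> pd.DataFrame:
    """One row per configured pair with its object-frame Euclidean distance (mm)."""
    rows = [
        {"keypoint_a": a, "keypoint_b": b, "distance_mm": spec.pair_distance(a, b)}
        for a, b in spec.pairs
    ]
    return pd.DataFrame(rows)


def place_object(spec: TestObjectSpec, pose: RigidPose) -> dict[str, np.ndarray]:
    """World coordinates of every keypoint under a rigid pose."""
    return {
        name: pose.rotation @ p + pose.translation for name, p in spec.keypoints.items()
    }


# ---------------------------------------------------------------------------
# JSON serialisation (object frame, mm)
# ---------------------------------------------------------------------------

def write_object_json(spec: TestObjectSpec, path) -> None:
    payload = {
        "name": spec.name,
        "keypoints": {k: list(map(float, v)) for k, v in spec.keypoints.items()},
        "pairs": [list(p) for p in spec.pairs],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_object_json(path) -> TestObjectSpec:
    payload = json.loads(Path(path).read_text())
    return TestObjectSpec(
        name=payload["name"],
        keypoints={k: np.asarray(v, dtype=float) for k, v in payload["keypoints"].items()},
        pairs=[tuple(p) for p in payload.get("pairs", [])],
    )
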