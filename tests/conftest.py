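import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rigval import (
    Camera,
    CameraIntrinsics,
    CameraPose,
    RigLayout,
    TrajectoryConfig,
    build_rig,
    simulate_bundle,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def plain_intrinsics():
    """1000 px focal, principal point (640, 400), no distortion."""
    return CameraIntrinsics(1000.0, 1000.0, 640.0, 400.0)


@pytest.fixture
def simple_camera(plain_intrinsics):
    """Identity-pose camera looking along world +z."""
    return Camera("cam", plain_intrinsics, CameraPose(np.eye(3), np.zeros(3)))


@pytest.fixture
def stereo_cameras(plain_intrinsics):
    """Two parallel cameras with a 100 mm x-baseline, both looking +z."""
    a = Camera("a", plain_intrinsics, CameraPose(np.eye(3), np.zeros(3)))
    b = Camera(
        "b", plain_intrinsics, CameraPose(np.eye(3), np.array([-100.0, 0.0, 0.0]))
    )
    return [a, b]


@pytest.fixture(scope="session")
def small_rig():
    return build_rig(RigLayout.small_arena())


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Small-arena session with zero noise and zero dropout, 40 frames."""
    return simulate_bundle(seed=7, trajectory=TrajectoryConfig(n_frames=40))
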