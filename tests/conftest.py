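"""Shared fixtures: a calibrated stereo rig and simulated recordings."""

import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from stereogait.stereo_geometry import CameraIntrinsics, StereoRig

hypothesis_settings.register_profile("repeatable", derandomize=True)
hypothesis_settings.load_profile("repeatable")
from stereogait.synthetic_gait import (
    GaitConfig,
    SceneConfig,
    render_cameras,
    render_reference,
    simulate_walk,
)


def make_rig(baseline: float = 1.8, convergence_deg: float = 12.0) -> StereoRig:
    """A convergent stereo pair with mild distortion, baseline along x."""
    cam = CameraIntrinsics(
        fx=1000.0, fy=1005.0, cx=640.0, cy=360.0,
        k1=-0.03, k2=0.004, p1=2e-4, p2=-1e-4,
        width=1280, height=720,
    )
    a = np.deg2rad(convergence_deg)
    # camera B rotated toward camera A about the vertical (y) axis
    R = np.array([
        [np.cos(a), 0.0, -np.sin(a)],
        [0.0, 1.0, 0.0],
        [np.sin(a), 0.0, np.cos(a)],
    ])
    t = R @ np.array([-baseline, 0.0, 0.0])
    return StereoRig(camA=cam, camB=cam, R=R, t=t)


@pytest.fixture(scope="session")
def rig() -> StereoRig:
    return make_rig()


NOISE_FREE_SCENE = SceneConfig(
    pixel_noise_sd=0.0, dropout_prob=0.0, occlusion_extra_noise=0.0,
    lag_frames=0, ref_noise_sd=0.0,
)


@pytest.fixture(scope="session")
def walk_gt():
    """One deterministic straight walk (8 steps) at the default gait."""
    return simulate_walk(GaitConfig(seed=7, n_steps=8))


@pytest.fixture(scope="session")
def noise_free_recording(walk_gt):
    """(keypoints A, keypoints B, rig, reference) without any noise or lag."""
    a, b, cam_rig = render_cameras(walk_gt, NOISE_FREE_SCENE)
    ref = render_reference(walk_gt, NOISE_FREE_SCENE)
    return a, b, cam_rig, ref


@pytest.fixture(scope="session")
def noisy_recording(walk_gt):
    """Same walk rendered with the default noise model and time offset."""
    scene = SceneConfig()
    a, b, cam_rig = render_cameras(walk_gt, scene)
    ref = render_reference(walk_gt, scene)
    return a, b, cam_rig, ref, scene
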