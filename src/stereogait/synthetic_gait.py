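"""Synthetic walking-lab generator with known ground truth.

No public dataset accompanies the measurement chain, so this module stands
in for the laboratory: a kinematic walking avatar with configurable step
length, cadence, stance fraction and path direction; a marker-based
reference renderer (100 Hz, 0.2 mm noise); and a two-webcam keypoint
renderer (30 Hz) with lens distortion, pixel noise, keypoint dropout,
resolution scaling and a known inter-system time offset.  Every rendered
artifact uses the exact formats the pipeline consumes, and every output is
a pure function of the configurations and the seed.

Avatar kinematics
-----------------
Walking is modeled as alternating single-support: the stance ankle is
stationary on the ground while the swing ankle advances two step lengths
along the path with the smooth profile ``s(tau) = 2L (tau - sin(2 pi
tau) / (2 pi))`` and a 5 cm vertical lift ``0.05 sin(pi tau)``,
``tau in [0, 1]`` over the swing duration ``(1 - stance_fraction) x
stride_time``.  Both ankles travel on the path line (zero step width), so
every true step length equals the configured value exactly — the
bookkeeping the recovery tests rely on.  The pelvis rides at the ankles'
mean path coordinate with a 2 cm vertical sinusoid at stride frequency;
hips sit +-10 cm laterally off the pelvis, knees interpolate 45%/55%
between hip and ankle with a 3 cm forward bump peaking mid-swing,
shoulders hang 0.30 x height above the hips, arms swing anti-phase
(+-20 degrees) and the face keypoints ride fixed offsets from the neck.

A standing prologue precedes the walk, during which the right wrist taps
the right hip ``tap_count`` times at ``tap_period`` spacing — the
synchronization gesture both systems observe.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .gait_events import StepRecord
from .io_formats import (
    COCO18_INDEX,
    COCO18_NAMES,
    N_JOINTS,
    KeypointSeries,
    write_calibration,
    write_openpose_dir,
    write_trajectory_table,
)
from .io_formats import TrajectoryTable
from .stereo_geometry import CameraIntrinsics, StereoRig, project_to_pixels
from .sync_align import RigidTransform

GT_RATE_HZ = 100.0
CAMERA_RATE_HZ = 30.0

#: Native webcam sensor model shared by both cameras (full HD, mild optics).
NATIVE_INTRINSICS = dict(
    fx=1400.0, fy=1400.0, cx=960.0, cy=540.0,
    k1=-0.02, k2=0.005, k3=0.0, p1=1e-4, p2=-1e-4,
    width=1920, height=1080,
)

RESOLUTIONS = {"HR": (1312, 736), "LR": (640, 480)}

#: Joints on each body side (shoulder, elbow, wrist, hip, knee, ankle, eye, ear).
LEFT_JOINTS = (5, 6, 7, 11, 12, 13, 15, 17)
RIGHT_JOINTS = (2, 3, 4, 8, 9, 10, 14, 16)


@dataclass
class GaitConfig:
    """Spatio-temporal program of one walking trial."""

    step_length: float = 0.60        # m
    cadence: float = 100.0           # steps/min
    stance_fraction: float = 0.60    # fraction of the stride in stance
    direction_deg: float = 0.0       # 0 = straight (camera-perpendicular) path
    n_steps: int = 5                 # steps collected per recording
    subject_height: float = 1.73     # m
    tap_count: int = 3               # synchronization taps in the prologue
    tap_period: float = 0.8          # s between taps
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step_length <= 0:
            raise ValueError("step_length must be positive")
        if not (0.4 <= self.stance_fraction <= 0.8):
            raise ValueError("stance_fraction must lie in [0.4, 0.8]")
        if self.n_steps < 4:
            raise ValueError("need at least 4 steps")

    @property
    def step_time(self) -> float:
        return 60.0 / self.cadence

    @property
    def stride_time(self) -> float:
        return 2.0 * self.step_time

    @property
    def swing_time(self) -> float:
        return (1.0 - self.stance_fraction) * self.stride_time

    @property
    def stance_time(self) -> float:
        return self.stance_fraction * self.stride_time


@dataclass
class SceneConfig:
    """Camera rig, noise model and timing of one recording session."""

    baseline: float = 1.8            # m between the two cameras
    camera_height: float = 2.3       # m above the ground
    camera_pitch_deg: float | None = None  # None: auto-aim at the mid-path point
    resolution_mode: str = "HR"      # HR (1312x736) | LR (640x480)
    pixel_noise_sd: float = 2.0      # px, keypoint localization noise
    dropout_prob: float = 0.02       # per joint per frame per camera
    occlusion_extra_noise: float = 4.0  # px, far-side joints on diagonal paths
    lag_frames: int = 3              # markerless stream delay at 30 Hz
    ref_noise_sd: float = 0.0002     # m, reference marker reconstruction noise

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if not (0.0 <= self.dropout_prob <= 1.0):
            raise ValueError("dropout_prob must be a probability")
        if self.resolution_mode not in RESOLUTIONS:
            raise ValueError(f"resolution_mode must be one of {sorted(RESOLUTIONS)}")


@dataclass
class GroundTruthRecording:
    """A simulated trial: 100 Hz joint trajectories plus exact gait truth."""

    gait: GaitConfig
    joints: np.ndarray               # (T, 18, 3) lab frame, meters
    frame_rate: float
    heel_strikes: dict[str, list[tuple[float, np.ndarray]]]  # foot -> [(t, pos)]
    toe_offs: dict[str, list[float]]
    true_steps: list[StepRecord]
    path_origin: np.ndarray
    path_dir: np.ndarray             # unit vector, ground plane
    walk_start: float                # s, end of the tap prologue
    tap_times: list[float]

    @property
    def duration(self) -> float:
        return (len(self.joints) - 1) / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.joints)) / self.frame_rate


# --------------------------------------------------------------------------
# Avatar kinematics
# --------------------------------------------------------------------------

def _swing_profile(tau: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalized swing: fraction of the 2L advance, and vertical lift (m)."""
    tau = np.clip(tau, 0.0, 1.0)
    advance = tau - np.sin(2 * np.pi * tau) / (2 * np.pi)
    lift = 0.05 * np.sin(np.pi * tau)
    return advance, lift


def _ankle_path(t: np.ndarray, swing_starts: np.ndarray, swing_dur: float,
                start_s: float, L: float) -> tuple[np.ndarray, np.ndarray]:
    """Path coordinate and height of one ankle over time."""
    s = np.full(len(t), start_s)
    z = np.zeros(len(t))
    for n, t_on in enumerate(swing_starts):
        tau = (t - t_on) / swing_dur
        during = (tau > 0) & (tau < 1)
        after = tau >= 1
        adv, lift = _swing_profile(tau[during])
        s[during] = start_s + 2 * L * n + 2 * L * adv
        z[during] = lift
        s[after] = start_s + 2 * L * (n + 1)
    return s, z


def simulate_walk(cfg: GaitConfig) -> GroundTruthRecording:
    """Generate one ground-truth walking trial at 100 Hz in the lab frame.

    The lab frame has its origin midway between the cameras at ground
    level: x along the camera bar, y pointing into the room (toward the
    walker), z up.  The path is centered 4 m from the camera bar and
    rotated by ``direction_deg`` about the vertical; the subject walks
    toward the cameras.  Deterministic given the configuration (the seed
    only matters to the renderers).
    """
    L = cfg.step_length
    H = cfg.subject_height
    swing_dur = cfg.swing_time
    stride = cfg.stride_time

    prologue = cfg.tap_count * cfg.tap_period + 1.0
    t0 = prologue
    n_right = (cfg.n_steps + 1) // 2
    n_left = cfg.n_steps // 2
    right_swings = t0 + np.arange(n_right) * stride
    left_swings = t0 + cfg.step_time + np.arange(n_left) * stride
    last_hs = max(right_swings[-1], left_swings[-1]) + swing_dur
    total = last_hs + 0.6   # standing tail keeps the window ending in stance
    t = np.arange(0.0, total + 0.5 / GT_RATE_HZ, 1.0 / GT_RATE_HZ)

    theta = np.deg2rad(cfg.direction_deg)
    # straight path runs along -y (toward the cameras); rotate about z
    path_dir = np.array([np.sin(theta), -np.cos(theta), 0.0])
    lateral = np.array([np.cos(theta), np.sin(theta), 0.0])  # subject's left
    # path ends 2.2 m from the camera bar so the subject stays 2-6 m away
    walk_dist = (cfg.n_steps + 1) * L
    mid_path = np.array([0.0, 2.2 + walk_dist / 2.0, 0.0])
    path_origin = mid_path - path_dir * walk_dist / 2.0

    sR, zR = _ankle_path(t, right_swings, swing_dur, 0.0, L)
    sL, zL = _ankle_path(t, left_swings, swing_dur, L, L)
    ankle_h = 0.05 * H  # ankle joint center above the sole

    def on_path(s: np.ndarray, z: np.ndarray, side: float = 0.0) -> np.ndarray:
        return (path_origin[None, :] + s[:, None] * path_dir[None, :]
                + side * lateral[None, :]
                + z[:, None] * np.array([0.0, 0.0, 1.0]))

    J = np.zeros((len(t), N_JOINTS, 3))
    J[:, COCO18_INDEX["RAnkle"]] = on_path(sR, zR + ankle_h)
    J[:, COCO18_INDEX["LAnkle"]] = on_path(sL, zL + ankle_h)

    walking = (t >= t0) & (t <= last_hs)
    phase = 2 * np.pi * (t - t0) / stride
    s_pelvis = 0.5 * (sR + sL)
    z_pelvis = 0.53 * H + 0.02 * np.where(walking, np.sin(2 * phase), 0.0)
    pelvis = on_path(s_pelvis, z_pelvis)
    J[:, COCO18_INDEX["RHip"]] = pelvis - 0.10 * lateral
    J[:, COCO18_INDEX["LHip"]] = pelvis + 0.10 * lateral

    # knees: 45% hip / 55% ankle with a forward bump peaking mid-swing
    for side, swings in (("R", right_swings), ("L", left_swings)):
        hip = J[:, COCO18_INDEX[f"{side}Hip"]]
        ankle = J[:, COCO18_INDEX[f"{side}Ankle"]]
        bump = np.zeros(len(t))
        for t_on in swings:
            tau = (t - t_on) / swing_dur
            m = (tau > 0) & (tau < 1)
            bump[m] = 0.03 * np.sin(np.pi * tau[m])
        J[:, COCO18_INDEX[f"{side}Knee"]] = (
            0.45 * hip + 0.55 * ankle + bump[:, None] * path_dir[None, :]
        )

    shoulder_lift = 0.30 * H
    J[:, COCO18_INDEX["RShoulder"]] = (
        J[:, COCO18_INDEX["RHip"]] + [0, 0, shoulder_lift] - 0.05 * lateral
    )
    J[:, COCO18_INDEX["LShoulder"]] = (
        J[:, COCO18_INDEX["LHip"]] + [0, 0, shoulder_lift] + 0.05 * lateral
    )
    neck = 0.5 * (J[:, COCO18_INDEX["RShoulder"]] + J[:, COCO18_INDEX["LShoulder"]])
    J[:, COCO18_INDEX["Neck"]] = neck

    # arms: pendular +-20 degrees, anti-phase, ramped in over the first 0.5 s
    upper, fore = 0.186 * H, 0.146 * H
    ramp = np.clip((t - t0) / 0.5, 0.0, 1.0) * np.clip((last_hs + 0.3 - t) / 0.3, 0.0, 1.0)
    swing_angle = np.deg2rad(20.0) * np.sin(phase) * ramp
    up = np.array([0.0, 0.0, 1.0])
    for side, sign in (("R", 1.0), ("L", -1.0)):
        ang = sign * swing_angle
        sh = J[:, COCO18_INDEX[f"{side}Shoulder"]]
        hang = (np.sin(ang)[:, None] * path_dir[None, :]
                - np.cos(ang)[:, None] * up[None, :])
        elbow = sh + upper * hang
        hang2 = (np.sin(1.3 * ang)[:, None] * path_dir[None, :]
                 - np.cos(1.3 * ang)[:, None] * up[None, :])
        wrist = elbow + fore * hang2
        J[:, COCO18_INDEX[f"{side}Elbow"]] = elbow
        J[:, COCO18_INDEX[f"{side}Wrist"]] = wrist

    # face keypoints: fixed offsets from the neck in the walking frame
    head = 0.17 * H
    face = {
        "Nose": 0.05 * path_dir + head * up,
        "REye": 0.06 * path_dir - 0.03 * lateral + (head + 0.02) * up,
        "LEye": 0.06 * path_dir + 0.03 * lateral + (head + 0.02) * up,
        "REar": -0.08 * lateral + head * up,
        "LEar": 0.08 * lateral + head * up,
    }
    for name, off in face.items():
        J[:, COCO18_INDEX[name]] = neck + off[None, :]

    # prologue taps: the right hand is held raised in front of the hip and
    # beaten against it at each tap — a large-amplitude gesture both
    # systems can see even under heavy keypoint noise
    tap_times = [0.5 + (k + 0.5) * cfg.tap_period for k in range(cfg.tap_count)]
    iw, ih = COCO18_INDEX["RWrist"], COCO18_INDEX["RHip"]
    bump = np.zeros(len(t))
    half = 0.45 * cfg.tap_period
    for tk in tap_times:
        m = np.abs(t - tk) < half
        bump[m] = np.maximum(bump[m], 0.5 * (1 + np.cos(np.pi * (t[m] - tk) / half)))
    pre = t < t0
    hang = J[pre, iw]
    ready = J[pre, ih] + 0.25 * path_dir[None, :] + 0.15 * up[None, :]
    # lower the hand back to its hanging rest over the last 0.4 s
    settle = np.clip((t0 - t[pre]) / 0.4, 0.0, 1.0)[:, None]
    rest = hang + settle * (ready - hang)
    J[pre, iw] = (1 - bump[pre, None]) * rest + bump[pre, None] * J[pre, ih]

    # ground-truth events and per-step bookkeeping
    heel_strikes: dict[str, list[tuple[float, np.ndarray]]] = {"left": [], "right": []}
    toe_offs: dict[str, list[float]] = {"left": [], "right": []}
    for foot, swings, start_s in (("right", right_swings, 0.0),
                                  ("left", left_swings, L)):
        for n, t_on in enumerate(swings):
            toe_offs[foot].append(float(t_on))
            pos = (path_origin + (start_s + 2 * L * (n + 1)) * path_dir
                   + np.array([0, 0, ankle_h]))
            heel_strikes[foot].append((float(t_on + swing_dur), pos))

    true_steps: list[StepRecord] = []
    all_hs = sorted(
        [(tk, foot, pos) for foot in ("left", "right")
         for tk, pos in heel_strikes[foot]]
    )
    for foot in ("left", "right"):
        hs = heel_strikes[foot]
        for (t_prev, _), (t_cur, pos_cur) in zip(hs, hs[1:]):
            prev_opp = [
                (tk, p) for tk, f, p in all_hs if f != foot and tk < t_cur
            ]
            step_len = None
            if prev_opp:
                step_len = float(np.linalg.norm((pos_cur - prev_opp[-1][1])[:2]))
            true_steps.append(StepRecord(
                foot=foot,
                heel_strike_time=t_cur,
                heel_strike_position=pos_cur,
                step_length=step_len,
                stance_time=cfg.stance_time,
                swing_time=cfg.swing_time,
                complete=True,
                stride_length=2 * L,
            ))
    true_steps.sort(key=lambda r: r.heel_strike_time)

    return GroundTruthRecording(
        gait=cfg, joints=J, frame_rate=GT_RATE_HZ,
        heel_strikes=heel_strikes, toe_offs=toe_offs, true_steps=true_steps,
        path_origin=path_origin, path_dir=path_dir, walk_start=t0,
        tap_times=tap_times,
    )


# --------------------------------------------------------------------------
# Renderers
# --------------------------------------------------------------------------

def render_reference(gt: GroundTruthRecording, scene: SceneConfig) -> TrajectoryTable:
    """Emulate the marker-based reference: 100 Hz, isotropic 0.2 mm noise."""
    rng = np.random.default_rng(np.random.SeedSequence([gt.gait.seed, 1]))
    xyz = gt.joints.copy()
    if scene.ref_noise_sd > 0:
        xyz = xyz + rng.normal(0.0, scene.ref_noise_sd, size=xyz.shape)
    T = len(xyz)
    return TrajectoryTable(
        system_id="reference", frame_rate=gt.frame_rate,
        joint_names=COCO18_NAMES, xyz=xyz,
        valid=np.ones((T, N_JOINTS), dtype=bool), frame_ref="lab",
    )


def _camera_pose(center: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation (lab -> camera) for a camera at *center* aimed at *target*.

    Camera axes: z forward (optical axis), x right, y down.
    """
    forward = target - center
    forward = forward / np.linalg.norm(forward)
    up = np.array([0.0, 0.0, 1.0])
    right = np.cross(forward, up)
    right = right / np.linalg.norm(right)
    down = np.cross(forward, right)
    return np.stack([right, down, forward])


def build_rig(gt: GroundTruthRecording, scene: SceneConfig) -> tuple[
    StereoRig, RigidTransform, RigidTransform
]:
    """Construct the stereo rig and the lab->camera transforms.

    Cameras sit at the ends of a bar of length ``baseline`` along the lab
    x axis at ``camera_height``; each is aimed at the mid-path point at
    chest height (auto pitch), or pitched explicitly when
    ``camera_pitch_deg`` is set.
    """
    w, h = RESOLUTIONS[scene.resolution_mode]
    native = CameraIntrinsics(**NATIVE_INTRINSICS)
    cam = native.scaled(w, h)
    cA = np.array([-scene.baseline / 2, 0.0, scene.camera_height])
    cB = np.array([+scene.baseline / 2, 0.0, scene.camera_height])
    mid_path = gt.path_origin + gt.path_dir * (
        (gt.gait.n_steps + 1) * gt.gait.step_length / 2.0
    )
    if scene.camera_pitch_deg is None:
        target = mid_path + np.array([0.0, 0.0, 0.6 * gt.gait.subject_height])
    else:
        pitch = np.deg2rad(scene.camera_pitch_deg)
        reach = np.linalg.norm(mid_path[:2])
        target_z = scene.camera_height - reach * np.tan(pitch)
        target = np.array([0.0, mid_path[1], target_z])
    RA = _camera_pose(cA, target)
    RB = _camera_pose(cB, target)
    rig = StereoRig(camA=cam, camB=cam, R=RB @ RA.T, t=RB @ (cA - cB))
    labA = RigidTransform(RA, -RA @ cA, "lab", "cameraA")
    labB = RigidTransform(RB, -RB @ cB, "lab", "cameraB")
    return rig, labA, labB


def render_cameras(
    gt: GroundTruthRecording, scene: SceneConfig
) -> tuple[KeypointSeries, KeypointSeries, StereoRig]:
    """Render the two 30 Hz keypoint streams through the stereo rig.

    The markerless clock starts ``lag_frames`` frames late relative to the
    reference: camera frame ``k`` shows the scene at ground-truth time
    ``(k + lag_frames) / 30``.  Each visible joint is projected with
    distortion, perturbed with Gaussian pixel noise (plus the extra
    occlusion noise on far-side joints when the path is diagonal), dropped
    with probability ``dropout_prob`` (confidence 0), and otherwise given
    a confidence drawn from U(0.4, 1.0).
    """
    rig, labA, labB = build_rig(gt, scene)
    rng = np.random.default_rng(np.random.SeedSequence([gt.gait.seed, 2]))
    dt = 1.0 / CAMERA_RATE_HZ
    n_frames = int(np.floor((gt.duration - scene.lag_frames * dt) / dt)) + 1
    if n_frames < 10:
        raise ValueError("recording too short for the requested lag")
    t_cam = (np.arange(n_frames) + scene.lag_frames) * dt
    t_cam = np.clip(t_cam, 0.0, gt.duration)

    # sample ground truth at camera timestamps (linear interp at 100 Hz)
    gt_t = gt.times
    pose = np.empty((n_frames, N_JOINTS, 3))
    for j in range(N_JOINTS):
        for c in range(3):
            pose[:, j, c] = np.interp(t_cam, gt_t, gt.joints[:, j, c])

    if gt.gait.direction_deg > 0:
        far = np.array(LEFT_JOINTS)
    elif gt.gait.direction_deg < 0:
        far = np.array(RIGHT_JOINTS)
    else:
        far = np.array([], dtype=int)

    w, h = RESOLUTIONS[scene.resolution_mode]
    series = []
    for cam_label, lab2cam in (("cameraA", labA), ("cameraB", labB)):
        cam = rig.camA
        uv = np.zeros((n_frames, N_JOINTS, 2))
        conf = np.zeros((n_frames, N_JOINTS))
        lost_frames = []
        for k in range(n_frames):
            Xc = lab2cam.apply(pose[k])
            in_front = Xc[:, 2] > 0.1
            px = np.zeros((N_JOINTS, 2))
            if in_front.any():
                px[in_front] = project_to_pixels(Xc[in_front], cam)
            visible = (
                in_front
                & (px[:, 0] >= 0) & (px[:, 0] < w)
                & (px[:, 1] >= 0) & (px[:, 1] < h)
            )
            if not visible.any():
                lost_frames.append(k)
                continue
            noise = rng.normal(0.0, scene.pixel_noise_sd, size=(N_JOINTS, 2))
            if far.size and scene.occlusion_extra_noise > 0:
                noise[far] += rng.normal(
                    0.0, scene.occlusion_extra_noise, size=(len(far), 2)
                )
            keep = visible & (rng.random(N_JOINTS) >= scene.dropout_prob)
            uv[k, keep] = px[keep] + noise[keep]
            conf[k, keep] = rng.uniform(0.4, 1.0, size=keep.sum())
        if len(lost_frames) == n_frames:
            raise ValueError(
                f"subject outside the {cam_label} frustum at frames {lost_frames[:10]}..."
            )
        series.append(KeypointSeries(
            camera_id=cam_label, frame_rate=CAMERA_RATE_HZ,
            resolution=(w, h), uv=uv, conf=conf,
        ))
    return series[0], series[1], rig


# --------------------------------------------------------------------------
# Factorial batch
# --------------------------------------------------------------------------

SUBJECT_HEIGHTS = (1.73, 1.82)
DIAGONAL_DIRECTION_DEG = 30.0


def batch_configs(
    replicates: int = 3,
    subjects: int = 2,
    seed: int = 0,
    gait: GaitConfig | None = None,
    scene: SceneConfig | None = None,
) -> list[dict]:
    """Enumerate the full 2x2x2 factorial design as configuration rows.

    Factors: gait direction (straight / diagonal), camera baseline
    (1.0 / 1.8 m) and resolution (LR / HR), each replicated
    ``replicates`` times per subject — 48 recordings at the defaults.
    Factor levels are also returned +-1-coded for the ANOVA (straight,
    1.0 m and LR are the -1 levels).  Seeds are drawn from one seed
    sequence, all distinct and below 2**31.
    """
    base_gait = gait if gait is not None else GaitConfig()
    base_scene = scene if scene is not None else SceneConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    rows = []
    run = 0
    for direction in ("straight", "diagonal"):
        for baseline in (1.0, 1.8):
            for resolution in ("LR", "HR"):
                for subject in range(subjects):
                    for rep in range(replicates):
                        rec_seed = int(rng.integers(0, 2**31 - 1))
                        g = replace(
                            base_gait,
                            direction_deg=(
                                DIAGONAL_DIRECTION_DEG if direction == "diagonal"
                                else 0.0
                            ),
                            subject_height=SUBJECT_HEIGHTS[
                                subject % len(SUBJECT_HEIGHTS)
                            ],
                            seed=rec_seed,
                        )
                        s = replace(
                            base_scene, baseline=baseline,
                            resolution_mode=resolution,
                        )
                        rows.append({
                            "run_id": f"run{run:03d}",
                            "direction": direction,
                            "baseline_m": baseline,
                            "resolution": resolution,
                            "subject": subject,
                            "replicate": rep,
                            "seed": rec_seed,
                            "x1": 1.0 if direction == "diagonal" else -1.0,
                            "x2": 1.0 if baseline == 1.8 else -1.0,
                            "x3": 1.0 if resolution == "HR" else -1.0,
                            "gait": g,
                            "scene": s,
                        })
                        run += 1
    return rows


def write_recording(
    gt: GroundTruthRecording,
    scene: SceneConfig,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Render one recording and write every pipeline input to *out_dir*."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    a, b, rig = render_cameras(gt, scene)
    ref = render_reference(gt, scene)
    paths = {
        "camera_a": out_dir / "camera_a",
        "camera_b": out_dir / "camera_b",
        "reference": out_dir / "reference.csv",
        "calibration": out_dir / "calibration.json",
        "ground_truth": out_dir / "ground_truth.json",
    }
    write_openpose_dir(a, paths["camera_a"])
    write_openpose_dir(b, paths["camera_b"])
    write_trajectory_table(ref, paths["reference"])
    write_calibration(rig, paths["calibration"])
    truth = {
        "gait": {k: getattr(gt.gait, k) for k in (
            "step_length", "cadence", "stance_fraction", "direction_deg",
            "n_steps", "subject_height", "tap_count", "tap_period", "seed",
        )},
        "scene": {k: getattr(scene, k) for k in (
            "baseline", "camera_height", "resolution_mode", "pixel_noise_sd",
            "dropout_prob", "occlusion_extra_noise", "lag_frames",
            "ref_noise_sd",
        )},
        "heel_strikes": {
            foot: [[tk, list(pos)] for tk, pos in ev]
            for foot, ev in gt.heel_strikes.items()
        },
        "toe_offs": gt.toe_offs,
        "true_steps": [
            {
                "foot": s.foot, "heel_strike_time": s.heel_strike_time,
                "step_length": s.step_length, "stance_time": s.stance_time,
                "swing_time": s.swing_time,
            }
            for s in gt.true_steps
        ],
    }
    paths["ground_truth"].write_text(json.dumps(truth, indent=1))
    return paths


def simulate_batch(
    out_dir: str | Path,
    replicates: int = 3,
    subjects: int = 2,
    seed: int = 0,
    gait: GaitConfig | None = None,
    scene: SceneConfig | None = None,
) -> pd.DataFrame:
    """Render the full factorial dataset to disk and return its manifest.

    One sub-directory per recording (keypoint dirs for both cameras,
    reference CSV, calibration JSON, ground-truth JSON) plus a
    ``manifest.csv`` listing factor levels and seeds for every run.
    """
    out_dir = Path(out_dir)
    rows = batch_configs(replicates, subjects, seed, gait, scene)
    manifest = []
    for row in rows:
        gt = simulate_walk(row["gait"])
        run_dir = out_dir / row["run_id"]
        write_recording(gt, row["scene"], run_dir)
        manifest.append({
            k: row[k] for k in (
                "run_id", "direction", "baseline_m", "resolution",
                "subject", "replicate", "seed", "x1", "x2", "x3",
            )
        } | {"path": str(run_dir)})
    df = pd.DataFrame(manifest)
    df.to_csv(out_dir / "manifest.csv", index=False)
    return df
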