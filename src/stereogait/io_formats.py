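"""On-disk formats and core keypoint containers.

Reads and writes the three inputs of the measurement chain — per-frame
OpenPose-dialect keypoint JSON from each webcam, the marker-based reference
trajectory table, and the stereo calibration file — plus the step-record
table produced at the end of the pipeline.

Conventions
-----------
* Image coordinates: origin at the top-left pixel center, ``u`` rightward,
  ``v`` downward, units of pixels.
* All 3D coordinates are meters in a right-handed frame.
* The skeleton is the 18-keypoint COCO body model; a joint with confidence
  exactly 0 is *missing* and carries no usable coordinates.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

# --------------------------------------------------------------------------
# COCO-18 skeleton layout
# --------------------------------------------------------------------------

#: Joint names in COCO-18 slot order.
COCO18_NAMES: tuple[str, ...] = (
    "Nose", "Neck",
    "RShoulder", "RElbow", "RWrist",
    "LShoulder", "LElbow", "LWrist",
    "RHip", "RKnee", "RAnkle",
    "LHip", "LKnee", "LAnkle",
    "REye", "LEye", "REar", "LEar",
)

N_JOINTS = 18

#: name -> COCO-18 slot index (total bijection over the 18 slots).
COCO18_INDEX: dict[str, int] = {n: i for i, n in enumerate(COCO18_NAMES)}

# The 13 skeletal nodes used for metrological evaluation: the sternum marker
# corresponds to the Neck keypoint; shoulders, elbows, wrists, hips, knees
# and ankles map by side.  Face keypoints (Nose, eyes, ears) have no
# marker-based counterpart and are excluded.
EVAL_NODES: tuple[str, ...] = (
    "Neck",
    "RShoulder", "LShoulder",
    "RElbow", "LElbow",
    "RWrist", "LWrist",
    "RHip", "LHip",
    "RKnee", "LKnee",
    "RAnkle", "LAnkle",
)

#: Default evaluation node map: node name -> COCO-18 index, both systems.
DEFAULT_NODE_MAP: dict[str, int] = {n: COCO18_INDEX[n] for n in EVAL_NODES}


class FormatError(ValueError):
    """An on-disk artifact violates its schema."""


# --------------------------------------------------------------------------
# Containers
# --------------------------------------------------------------------------

@dataclass
class KeypointFrame:
    """One camera frame: 18 joint observations in pixels with confidences."""

    frame_index: int
    time_s: float
    uv: np.ndarray          # (18, 2) pixels; undefined where missing
    confidence: np.ndarray  # (18,) in [0, 1]; 0 marks a missing joint

    @property
    def missing(self) -> np.ndarray:
        return self.confidence == 0.0


@dataclass
class KeypointSeries:
    """A 30 Hz stream of 2D skeleton observations from one camera.

    Coordinates are stored as dense arrays; ``conf == 0`` flags missing
    joints, whose coordinates are meaningless and must not be used.
    """

    camera_id: str
    frame_rate: float
    resolution: tuple[int, int]      # (width, height) pixels
    uv: np.ndarray                   # (T, 18, 2) float
    conf: np.ndarray                 # (T, 18) float in [0, 1]

    def __post_init__(self) -> None:
        self.uv = np.asarray(self.uv, dtype=float)
        self.conf = np.asarray(self.conf, dtype=float)
        if self.uv.shape[1:] != (N_JOINTS, 2) or self.conf.shape[1:] != (N_JOINTS,):
            raise ValueError("KeypointSeries requires 18 joint slots per frame")
        if self.uv.shape[0] != self.conf.shape[0]:
            raise ValueError("uv and conf frame counts differ")

    def __len__(self) -> int:
        return self.uv.shape[0]

    @property
    def n_frames(self) -> int:
        return self.uv.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    @property
    def valid(self) -> np.ndarray:
        """(T, 18) bool mask of usable observations."""
        return self.conf > 0.0

    def frame(self, k: int) -> KeypointFrame:
        return KeypointFrame(k, k / self.frame_rate, self.uv[k], self.conf[k])


@dataclass
class TrajectoryTable:
    """Time-stamped 3D joint-center trajectories from one measurement system.

    The reference optoelectronic system emits these at 100 Hz in the
    laboratory frame; the markerless chain produces the same container after
    triangulation and alignment, which makes the two directly comparable.
    """

    system_id: str
    frame_rate: float
    joint_names: tuple[str, ...]
    xyz: np.ndarray    # (T, J, 3) meters
    valid: np.ndarray  # (T, J) bool
    frame_ref: str = "lab"

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.joint_names = tuple(self.joint_names)
        if self.xyz.ndim != 3 or self.xyz.shape[2] != 3:
            raise ValueError("xyz must have shape (T, J, 3)")
        if self.xyz.shape[:2] != self.valid.shape:
            raise ValueError("xyz and valid shapes disagree")
        if self.xyz.shape[1] != len(self.joint_names):
            raise ValueError("joint_names length does not match xyz")
        if np.any(~np.isfinite(self.xyz[self.valid])):
            raise ValueError("valid positions must be finite")

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def joint_index(self, name: str) -> int:
        try:
            return self.joint_names.index(name)
        except ValueError as exc:
            raise KeyError(f"joint {name!r} not present in {self.system_id}") from exc


# --------------------------------------------------------------------------
# OpenPose per-frame JSON dialect
# --------------------------------------------------------------------------

_FRAME_RE = re.compile(r"(\d+)")


def _frame_number(path: Path) -> int:
    m = _FRAME_RE.findall(path.stem)
    if not m:
        raise FormatError(f"cannot extract a frame number from {path.name!r}")
    return int(m[-1])


def _select_person(people: list[dict], policy: str, path: Path) -> np.ndarray:
    """Return the (54,) keypoint vector of the person chosen by *policy*."""
    flats = []
    for person in people:
        kp = np.asarray(person.get("pose_keypoints_2d", []), dtype=float)
        if kp.size != 3 * N_JOINTS:
            raise FormatError(
                f"{path}: pose_keypoints_2d has {kp.size} values, expected "
                f"{3 * N_JOINTS} (18-keypoint COCO body model required; "
                "BODY_25 exports are not supported)"
            )
        flats.append(kp)
    if len(flats) == 1:
        return flats[0]
    if policy == "error_if_multiple":
        raise FormatError(f"{path}: {len(flats)} people detected, expected one")
    if policy == "highest_total_confidence":
        totals = [f[2::3].sum() for f in flats]
        return flats[int(np.argmax(totals))]
    raise ValueError(f"unknown person_policy {policy!r}")


def read_openpose_dir(
    path: str | Path,
    person_policy: str = "highest_total_confidence",
    *,
    camera_id: str | None = None,
    frame_rate: float = 30.0,
    resolution: tuple[int, int] = (1312, 736),
) -> KeypointSeries:
    """Read a directory of per-frame OpenPose JSON files into one series.

    Each file holds ``{"people": [{"pose_keypoints_2d": [x0, y0, c0, ...]}]}``
    with 18 (x, y, confidence) triplets.  Frames with an empty ``people``
    list become all-missing frames; with several people, *person_policy*
    selects the one with the highest summed confidence or raises.
    """
    path = Path(path)
    files = sorted(
        (p for p in path.iterdir() if p.suffix == ".json"), key=_frame_number
    )
    if not files:
        raise FormatError(f"no per-frame JSON files in {path}")
    uv = np.zeros((len(files), N_JOINTS, 2))
    conf = np.zeros((len(files), N_JOINTS))
    for k, f in enumerate(files):
        try:
            doc = json.loads(f.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"malformed JSON in {f}: {exc}") from exc
        people = doc.get("people", [])
        if not people:
            continue  # all joints missing at this frame
        flat = _select_person(people, person_policy, f)
        uv[k] = flat.reshape(N_JOINTS, 3)[:, :2]
        conf[k] = flat[2::3]
    return KeypointSeries(
        camera_id=camera_id if camera_id is not None else path.name,
        frame_rate=frame_rate,
        resolution=resolution,
        uv=uv,
        conf=conf,
    )


def write_openpose_dir(series: KeypointSeries, path: str | Path) -> list[Path]:
    """Write one JSON file per frame; missing joints become (0, 0, 0)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []
    for k in range(series.n_frames):
        flat = np.zeros(3 * N_JOINTS)
        keep = series.conf[k] > 0.0
        flat[0::3][keep] = series.uv[k, keep, 0]
        flat[1::3][keep] = series.uv[k, keep, 1]
        flat[2::3][keep] = series.conf[k, keep]
        doc = {"version": 1.2, "people": [{"pose_keypoints_2d": flat.tolist()}]}
        out = path / f"frame_{k:06d}_keypoints.json"
        out.write_text(json.dumps(doc))
        written.append(out)
    return written


# --------------------------------------------------------------------------
# Trajectory tables (long CSV)
# --------------------------------------------------------------------------

_TRAJ_COLUMNS = ["frame", "time_s", "joint", "x_m", "y_m", "z_m", "valid"]


def read_trajectory_table(path: str | Path) -> TrajectoryTable:
    """Read a long-format trajectory CSV (schema: frame,time_s,joint,x_m,y_m,z_m,valid)."""
    df = pd.read_csv(path)
    missing = set(_TRAJ_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    joints = tuple(dict.fromkeys(df["joint"]))  # first-appearance order
    frames = np.sort(df["frame"].unique())
    if np.any(np.diff(frames) <= 0) or frames[0] != 0 or len(frames) != frames[-1] + 1:
        raise FormatError(f"{path}: frame indices must be 0..T-1 and monotone")
    t = df.drop_duplicates("frame").sort_values("frame")["time_s"].to_numpy()
    if len(t) > 1:
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], atol=1e-9):
            raise FormatError(f"{path}: frame rate is not constant")
        rate = 1.0 / dt[0]
    else:
        rate = 100.0
    T, J = len(frames), len(joints)
    xyz = np.full((T, J, 3), np.nan)
    valid = np.zeros((T, J), dtype=bool)
    jidx = {n: j for j, n in enumerate(joints)}
    fi = df["frame"].to_numpy()
    ji = df["joint"].map(jidx).to_numpy()
    xyz[fi, ji] = df[["x_m", "y_m", "z_m"]].to_numpy()
    valid[fi, ji] = df["valid"].to_numpy().astype(bool)
    xyz[~valid] = 0.0
    return TrajectoryTable(
        system_id=Path(path).stem, frame_rate=rate, joint_names=joints,
        xyz=xyz, valid=valid,
    )


def write_trajectory_table(table: TrajectoryTable, path: str | Path) -> None:
    T, J = table.valid.shape
    fi = np.repeat(np.arange(T), J)
    ji = np.tile(np.arange(J), T)
    df = pd.DataFrame(
        {
            "frame": fi,
            "time_s": fi / table.frame_rate,
            "joint": [table.joint_names[j] for j in ji],
            "x_m": table.xyz[fi, ji, 0],
            "y_m": table.xyz[fi, ji, 1],
            "z_m": table.xyz[fi, ji, 2],
            "valid": table.valid[fi, ji].astype(int),
        }
    )
    df.to_csv(path, index=False, float_format="%.9f")


# --------------------------------------------------------------------------
# Calibration files
# --------------------------------------------------------------------------

_CAM_KEYS = ("fx", "fy", "cx", "cy", "k1", "k2", "k3", "p1", "p2",
             "width", "height")


def _load_structured(path: Path) -> dict:
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        return yaml.safe_load(text)
    return json.loads(text)


def read_calibration(path: str | Path):
    """Read a stereo calibration file (JSON or YAML) into a :class:`StereoRig`.

    The file carries per-camera intrinsics (focal lengths, principal point,
    Brown–Conrady distortion, sensor size) and the relative pose of camera B
    with respect to camera A (rotation as a 3x3 matrix or axis-angle vector,
    translation in meters).  The rotation is re-orthonormalized when within
    1e-6 of orthonormal and rejected otherwise.
    """
    from .stereo_geometry import CameraIntrinsics, StereoRig, orthonormalize_rotation

    doc = _load_structured(Path(path))
    cams = {}
    for key in ("camera_a", "camera_b"):
        if key not in doc:
            raise FormatError(f"{path}: missing section {key!r}")
        entry = doc[key]
        missing = [k for k in _CAM_KEYS if k not in entry]
        if missing:
            raise FormatError(f"{path}: {key} missing fields {missing}")
        cams[key] = CameraIntrinsics(**{k: entry[k] for k in _CAM_KEYS})
    R = np.asarray(doc["rotation"], dtype=float)
    if R.shape == (3,):  # axis-angle
        from scipy.spatial.transform import Rotation
        R = Rotation.from_rotvec(R).as_matrix()
    elif R.shape != (3, 3):
        raise FormatError(f"{path}: rotation must be 3x3 or axis-angle length 3")
    R = orthonormalize_rotation(R, tol=1e-6)
    t = np.asarray(doc["translation"], dtype=float).reshape(3)
    return StereoRig(camA=cams["camera_a"], camB=cams["camera_b"], R=R, t=t)


def write_calibration(rig, path: str | Path) -> None:
    path = Path(path)
    doc = {
        "camera_a": {k: getattr(rig.camA, k) for k in _CAM_KEYS},
        "camera_b": {k: getattr(rig.camB, k) for k in _CAM_KEYS},
        "rotation": np.asarray(rig.R).tolist(),
        "translation": np.asarray(rig.t).tolist(),
    }
    if path.suffix in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(doc))
    else:
        path.write_text(json.dumps(doc, indent=1))


# --------------------------------------------------------------------------
# Step-record tables
# --------------------------------------------------------------------------

_STEP_COLUMNS = ["foot", "heel_strike_time_s", "step_length_m",
                 "stance_time_s", "swing_time_s"]


def write_step_records(steps, path: str | Path) -> None:
    """Write step records as CSV (schema: foot,heel_strike_time_s,step_length_m,stance_time_s,swing_time_s)."""
    rows = [
        {
            "foot": s.foot,
            "heel_strike_time_s": s.heel_strike_time,
            "step_length_m": s.step_length if s.step_length is not None else np.nan,
            "stance_time_s": s.stance_time if s.stance_time is not None else np.nan,
            "swing_time_s": s.swing_time if s.swing_time is not None else np.nan,
        }
        for s in steps
    ]
    pd.DataFrame(rows, columns=_STEP_COLUMNS).to_csv(
        path, index=False, float_format="%.9f"
    )


def read_step_records(path: str | Path):
    from .gait_events import StepRecord

    df = pd.read_csv(path)
    missing = set(_STEP_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")

    def _opt(x):
        return None if pd.isna(x) else float(x)

    return [
        StepRecord(
            foot=row.foot,
            heel_strike_time=float(row.heel_strike_time_s),
            heel_strike_position=None,
            step_length=_opt(row.step_length_m),
            stance_time=_opt(row.stance_time_s),
            swing_time=_opt(row.swing_time_s),
            complete=True,
        )
        for row in df.itertuples()
    ]
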