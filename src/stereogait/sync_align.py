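"""Temporal synchronization and rigid spatial alignment.

The webcams and the marker-based reference have no hardware trigger; the
subject instead taps the right wrist on the right hip a few times before
walking.  Both systems see the same wrist–hip distance signal, so after
downsampling the 100 Hz reference to the cameras' 30 Hz with cubic splines,
the integer frame lag that maximizes the normalized cross-correlation of
the two (mean-removed) signals synchronizes the streams.

Spatially, the triangulated skeleton lives in the camera-A frame while the
reference lives in the laboratory frame (origin midway between the cameras,
on the ground).  A single rigid transform — rotation from the Kabsch SVD
solution plus a translation — maps one into the other, estimated from all
frame x node correspondences stacked as one point set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline

from .io_formats import COCO18_INDEX, DEFAULT_NODE_MAP, TrajectoryTable
from .stereo_geometry import SkeletonSeries3D


@dataclass
class GestureSignal:
    """Scalar wrist-to-hip distance over time from one measurement system."""

    frame_rate: float
    values: np.ndarray   # (T,) meters
    valid: np.ndarray    # (T,) bool
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if np.any(self.values[self.valid] < 0):
            raise ValueError("distances must be non-negative where valid")


@dataclass
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` between two named frames."""

    R: np.ndarray
    t: np.ndarray
    from_frame: str
    to_frame: str

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        self.t = np.asarray(self.t, dtype=float).reshape(3)
        if np.abs(self.R.T @ self.R - np.eye(3)).max() > 1e-9:
            raise ValueError("R is not orthonormal to 1e-9")
        if np.linalg.det(self.R) < 0:
            raise ValueError("R is a reflection")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.R.T + self.t

    def inverse(self) -> "RigidTransform":
        return RigidTransform(
            self.R.T, -self.R.T @ self.t, self.to_frame, self.from_frame
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "R": self.R.tolist(), "t": self.t.tolist(),
            "from_frame": self.from_frame, "to_frame": self.to_frame,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RigidTransform":
        doc = json.loads(Path(path).read_text())
        return cls(np.array(doc["R"]), np.array(doc["t"]),
                   doc["from_frame"], doc["to_frame"])


# --------------------------------------------------------------------------
# Resampling
# --------------------------------------------------------------------------

def _resample_arrays(
    xyz: np.ndarray, valid: np.ndarray, src_rate: float, target_rate: float
) -> tuple[np.ndarray, np.ndarray]:
    T, J, _ = xyz.shape
    t_src = np.arange(T) / src_rate
    t_new = np.arange(0.0, t_src[-1] + 0.5 / target_rate, 1.0 / target_rate)
    t_new = t_new[t_new <= t_src[-1] + 1e-12]
    Tn = len(t_new)
    out = np.zeros((Tn, J, 3))
    out_valid = np.zeros((Tn, J), dtype=bool)
    for j in range(J):
        ok = valid[:, j]
        if ok.sum() < 4:
            raise ValueError(
                f"joint {j}: need >= 4 valid samples for cubic-spline resampling"
            )
        ts = t_src[ok]
        cs = CubicSpline(ts, xyz[ok, j, :], axis=0)
        out[:, j, :] = cs(t_new)
        # a target sample is valid only where its enclosing source samples are
        idx = np.searchsorted(t_src, t_new, side="right") - 1
        idx = np.clip(idx, 0, T - 2)
        enclosed = ok[idx] & ok[idx + 1]
        inside = (t_new >= ts[0] - 1e-12) & (t_new <= ts[-1] + 1e-12)
        out_valid[:, j] = enclosed & inside
    return out, out_valid


def resample_series(series, target_rate: float):
    """Cubic-spline resampling of a 3D series to *target_rate* (same type out).

    Validity propagates conservatively: a resampled sample is valid only
    when both source samples bracketing its timestamp are valid.
    """
    if series.frame_rate < target_rate:
        raise ValueError("resampling only downsamples or keeps the rate")
    if isinstance(series, SkeletonSeries3D):
        xyz, valid = _resample_arrays(
            series.xyz, series.valid, series.frame_rate, target_rate
        )
        return SkeletonSeries3D(target_rate, xyz, valid, series.frame_ref)
    if isinstance(series, TrajectoryTable):
        xyz, valid = _resample_arrays(
            series.xyz, series.valid, series.frame_rate, target_rate
        )
        return TrajectoryTable(
            series.system_id, target_rate, series.joint_names, xyz, valid,
            frame_ref=series.frame_ref,
        )
    raise TypeError(f"cannot resample {type(series).__name__}")


# --------------------------------------------------------------------------
# Gesture-based synchronization
# --------------------------------------------------------------------------

def gesture_signal(series) -> GestureSignal:
    """Per-frame Euclidean distance between right wrist and right hip."""
    if isinstance(series, SkeletonSeries3D):
        iw, ih = COCO18_INDEX["RWrist"], COCO18_INDEX["RHip"]
        source = f"skeleton3d[{series.frame_ref}]"
        jw = series.xyz[:, iw, :]
        jh = series.xyz[:, ih, :]
        ok = series.valid[:, iw] & series.valid[:, ih]
    elif isinstance(series, TrajectoryTable):
        iw = series.joint_index("RWrist")
        ih = series.joint_index("RHip")
        source = series.system_id
        jw = series.xyz[:, iw, :]
        jh = series.xyz[:, ih, :]
        ok = series.valid[:, iw] & series.valid[:, ih]
    else:
        raise TypeError(f"cannot extract gesture from {type(series).__name__}")
    d = np.linalg.norm(jw - jh, axis=1)
    d[~ok] = 0.0
    return GestureSignal(series.frame_rate, d, ok, source)


def estimate_lag(
    sigA: GestureSignal, sigB: GestureSignal, max_lag_frames: int = 150
) -> int:
    """Integer lag (frames) aligning ``sigA[k]`` with ``sigB[k + lag]``.

    Maximizes the normalized cross-correlation of the mean-removed signals
    over the valid overlap; ties break toward the smallest ``|lag|``.  Both
    signals must share the frame rate (nominally 30 Hz) and overlap by at
    least 2 s after shifting.
    """
    if abs(sigA.frame_rate - sigB.frame_rate) > 1e-9:
        raise ValueError("gesture signals must share a frame rate")
    min_overlap = int(round(2.0 * sigA.frame_rate))
    best: tuple[float, int] | None = None
    for lag in range(-max_lag_frames, max_lag_frames + 1):
        # sigA[k] ~ sigB[k + lag]
        ka0 = max(0, -lag)
        ka1 = min(len(sigA.values), len(sigB.values) - lag)
        if ka1 - ka0 < min_overlap:
            continue
        a = sigA.values[ka0:ka1]
        b = sigB.values[ka0 + lag:ka1 + lag]
        ok = sigA.valid[ka0:ka1] & sigB.valid[ka0 + lag:ka1 + lag]
        if ok.sum() < min_overlap:
            continue
        a = a[ok] - a[ok].mean()
        b = b[ok] - b[ok].mean()
        va, vb = a @ a, b @ b
        if va < 1e-12 or vb < 1e-12:
            continue
        r = (a @ b) / np.sqrt(va * vb)
        key = (r, -abs(lag))
        if best is None or key > best[0]:
            best = (key, lag)
    if best is None:
        raise ValueError("no gesture detected (flat or non-overlapping signals)")
    return best[1]


def shift_series(series, lag_frames: int):
    """Drop the first *lag_frames* frames (or pad-crop for negative lags)."""
    if lag_frames == 0:
        return series
    if isinstance(series, SkeletonSeries3D):
        if lag_frames > 0:
            return SkeletonSeries3D(
                series.frame_rate, series.xyz[lag_frames:],
                series.valid[lag_frames:], series.frame_ref,
            )
        raise ValueError("negative shift: shift the other series instead")
    if isinstance(series, TrajectoryTable):
        if lag_frames > 0:
            return TrajectoryTable(
                series.system_id, series.frame_rate, series.joint_names,
                series.xyz[lag_frames:], series.valid[lag_frames:],
                frame_ref=series.frame_ref,
            )
        raise ValueError("negative shift: shift the other series instead")
    raise TypeError(f"cannot shift {type(series).__name__}")


# --------------------------------------------------------------------------
# Rigid alignment (Kabsch)
# --------------------------------------------------------------------------

def kabsch(
    P: np.ndarray, Q: np.ndarray,
    from_frame: str = "source", to_frame: str = "target",
) -> RigidTransform:
    """Least-squares rigid transform mapping point set P onto Q.

    Standard SVD solution on the centered cross-covariance ``H = Pc^T Qc``:
    with ``H = U S V^T``, the rotation is ``R = V diag(1, 1, d) U^T`` where
    ``d = sign(det(V U^T))`` forbids reflections, and ``t = mean(Q) - R
    mean(P)``.  Requires at least 3 non-collinear correspondences.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matching (N, 3) arrays")
    if len(P) < 3:
        raise ValueError("need at least 3 correspondences")
    p_bar, q_bar = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - p_bar, Q - q_bar
    H = Pc.T @ Qc
    U, s, Vt = np.linalg.svd(H)
    if s[1] < 1e-12 * max(s[0], 1e-300):
        raise ValueError("correspondences are collinear; rotation is ambiguous")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d == 0:
        d = 1.0
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = q_bar - R @ p_bar
    return RigidTransform(R, t, from_frame, to_frame)


def _stack_correspondences(
    op_series: SkeletonSeries3D,
    ref_series: TrajectoryTable,
    node_map: dict[str, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    node_map = DEFAULT_NODE_MAP if node_map is None else node_map
    if op_series.n_frames != ref_series.n_frames:
        raise ValueError("series must be synchronized to equal length first")
    P, Q, used_nodes = [], [], set()
    for name, op_idx in node_map.items():
        ref_idx = ref_series.joint_index(name)
        ok = op_series.valid[:, op_idx] & ref_series.valid[:, ref_idx]
        if not ok.any():
            continue
        P.append(op_series.xyz[ok, op_idx, :])
        Q.append(ref_series.xyz[ok, ref_idx, :])
        used_nodes.add(name)
    if len(used_nodes) < 3:
        raise ValueError(
            f"only {len(used_nodes)} mapped nodes have valid correspondences; need >= 3"
        )
    return np.vstack(P), np.vstack(Q)


def build_lab_transform(
    op_series: SkeletonSeries3D,
    ref_series: TrajectoryTable,
    node_map: dict[str, int] | None = None,
) -> RigidTransform:
    """Rigid transform from the camera-A frame to the laboratory frame.

    One global Kabsch fit over every valid (frame x mapped node)
    correspondence between the synchronized series.  The laboratory origin
    (midway between the cameras, on the ground) is carried by the reference
    data's own frame.
    """
    P, Q = _stack_correspondences(op_series, ref_series, node_map)
    return kabsch(P, Q, from_frame=op_series.frame_ref,
                  to_frame=ref_series.frame_ref)


def apply_transform(series, T: RigidTransform):
    """Map every valid point of a series through *T*; validity untouched."""
    if series.frame_ref != T.from_frame:
        raise ValueError(
            f"series is in frame {series.frame_ref!r}, transform expects "
            f"{T.from_frame!r}"
        )
    new_xyz = series.xyz @ T.R.T + T.t
    if isinstance(series, SkeletonSeries3D):
        return SkeletonSeries3D(series.frame_rate, new_xyz,
                                series.valid.copy(), T.to_frame)
    if isinstance(series, TrajectoryTable):
        return TrajectoryTable(series.system_id, series.frame_rate,
                               series.joint_names, new_xyz,
                               series.valid.copy(), frame_ref=T.to_frame)
    raise TypeError(f"cannot transform {type(series).__name__}")
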