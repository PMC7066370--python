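"""Pinhole camera model, undistortion and two-view triangulation.

The markerless chain observes the walker with two calibrated webcams.  Each
camera follows the pinhole + Brown–Conrady model: a 3D point ``(x, y, z)``
in the camera frame projects to normalized coordinates ``x' = x/z``,
``y' = y/z``, is warped by radial ``(1 + k1 r^2 + k2 r^4 + k3 r^6)`` and
tangential ``(p1, p2)`` distortion, and lands on the sensor at
``u = fx x'' + cx``, ``v = fy y'' + cy``.  Triangulation inverts the pair of
projections: observations are undistorted to normalized coordinates and the
3D point is recovered by a linear (DLT) homogeneous least-squares solve with
camera matrices ``[I|0]`` and ``[R|t]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import N_JOINTS, KeypointSeries


@dataclass
class CameraIntrinsics:
    """Internal parameters of one camera (pixels and unitless distortion)."""

    fx: float
    fy: float
    cx: float
    cy: float
    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    p1: float = 0.0
    p2: float = 0.0
    width: int = 1312
    height: int = 736

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx <= self.width and 0 <= self.cy <= self.height):
            raise ValueError("principal point must lie inside the sensor")

    def scaled(self, width: int, height: int) -> "CameraIntrinsics":
        """Intrinsics for the same lens at a different output resolution."""
        sx, sy = width / self.width, height / self.height
        return CameraIntrinsics(
            fx=self.fx * sx, fy=self.fy * sy,
            cx=self.cx * sx, cy=self.cy * sy,
            k1=self.k1, k2=self.k2, k3=self.k3, p1=self.p1, p2=self.p2,
            width=width, height=height,
        )


def orthonormalize_rotation(R: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Project *R* onto SO(3) if it is within *tol* of orthonormal.

    Uses the polar decomposition (SVD with unit singular values); rejects
    matrices farther than *tol* from orthonormality and any reflection.
    """
    R = np.asarray(R, dtype=float)
    defect = np.abs(R.T @ R - np.eye(3)).max()
    if defect > tol:
        raise ValueError(f"rotation is {defect:.2e} from orthonormal (tol {tol:g})")
    U, _, Vt = np.linalg.svd(R)
    Rn = U @ Vt
    if np.linalg.det(Rn) <= 0:
        raise ValueError("matrix is a reflection, not a rotation (det <= 0)")
    return Rn


@dataclass
class StereoRig:
    """Two camera models and their relative rigid pose.

    ``R`` and ``t`` map camera-A coordinates to camera-B coordinates:
    ``X_B = R @ X_A + t`` (meters).
    """

    camA: CameraIntrinsics
    camB: CameraIntrinsics
    R: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        self.t = np.asarray(self.t, dtype=float).reshape(3)
        if np.abs(self.R.T @ self.R - np.eye(3)).max() > 1e-9:
            raise ValueError("R is not orthonormal to 1e-9")
        if np.linalg.det(self.R) < 0:
            raise ValueError("R is a reflection (det < 0)")
        if self.baseline <= 0:
            raise ValueError("cameras are coincident (zero baseline)")

    @property
    def baseline(self) -> float:
        """Distance between the two optical centers (m)."""
        # camera-B center in A coordinates is -R^T t
        return float(np.linalg.norm(self.R.T @ self.t))


@dataclass
class SkeletonSeries3D:
    """Time-stamped 3D positions of the 18 skeleton joints (meters)."""

    frame_rate: float
    xyz: np.ndarray     # (T, 18, 3)
    valid: np.ndarray   # (T, 18) bool
    frame_ref: str      # "cameraA" | "lab"

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.xyz.shape[1:] != (N_JOINTS, 3):
            raise ValueError("SkeletonSeries3D requires (T, 18, 3) positions")
        if self.valid.shape != self.xyz.shape[:2]:
            raise ValueError("validity mask shape mismatch")
        if np.any(~np.isfinite(self.xyz[self.valid])):
            raise ValueError("valid positions must be finite")

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def copy(self) -> "SkeletonSeries3D":
        return SkeletonSeries3D(
            self.frame_rate, self.xyz.copy(), self.valid.copy(), self.frame_ref
        )


# --------------------------------------------------------------------------
# Forward model
# --------------------------------------------------------------------------

def _distort_normalized(xn: np.ndarray, cam: CameraIntrinsics) -> np.ndarray:
    """Apply Brown–Conrady distortion to normalized coordinates (..., 2)."""
    x, y = xn[..., 0], xn[..., 1]
    r2 = x * x + y * y
    radial = 1.0 + r2 * (cam.k1 + r2 * (cam.k2 + r2 * cam.k3))
    xd = x * radial + 2 * cam.p1 * x * y + cam.p2 * (r2 + 2 * x * x)
    yd = y * radial + cam.p1 * (r2 + 2 * y * y) + 2 * cam.p2 * x * y
    return np.stack([xd, yd], axis=-1)


def project_to_pixels(points: np.ndarray, cam: CameraIntrinsics) -> np.ndarray:
    """Project 3D points in the camera frame to pixel coordinates.

    Points must be in front of the camera (``z > 0``).
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    z = pts[:, 2]
    if np.any(z <= 0):
        raise ValueError("point behind camera (z <= 0)")
    xn = pts[:, :2] / z[:, None]
    xd = _distort_normalized(xn, cam)
    uv = np.empty_like(xd)
    uv[:, 0] = cam.fx * xd[:, 0] + cam.cx
    uv[:, 1] = cam.fy * xd[:, 1] + cam.cy
    return uv[0] if single else uv


def undistort_to_normalized(
    points: np.ndarray,
    cam: CameraIntrinsics,
    tol: float = 1e-10,
    max_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Invert projection + distortion: pixels -> normalized coordinates.

    The distortion model has no closed-form inverse; a fixed-point
    iteration ``x <- (x_d - tangential(x)) / radial(x)`` is run from the
    distorted point.  Non-converged points (wild distortion) are flagged
    invalid rather than raising.

    Returns ``(normalized (..., 2), converged (...,) bool)``.
    """
    uv = np.asarray(points, dtype=float)
    single = uv.ndim == 1
    uv = np.atleast_2d(uv)
    xd = np.empty_like(uv)
    xd[:, 0] = (uv[:, 0] - cam.cx) / cam.fx
    xd[:, 1] = (uv[:, 1] - cam.cy) / cam.fy
    x = xd.copy()
    converged = np.zeros(len(x), dtype=bool)
    for _ in range(max_iter):
        xx, yy = x[:, 0], x[:, 1]
        r2 = xx * xx + yy * yy
        radial = 1.0 + r2 * (cam.k1 + r2 * (cam.k2 + r2 * cam.k3))
        dx = 2 * cam.p1 * xx * yy + cam.p2 * (r2 + 2 * xx * xx)
        dy = cam.p1 * (r2 + 2 * yy * yy) + 2 * cam.p2 * xx * yy
        x_new = np.empty_like(x)
        x_new[:, 0] = (xd[:, 0] - dx) / radial
        x_new[:, 1] = (xd[:, 1] - dy) / radial
        step = np.abs(x_new - x).max(axis=1)
        x = x_new
        converged = step < tol
        if converged.all():
            break
    bad = ~np.isfinite(x).all(axis=1)
    converged &= ~bad
    x[bad] = 0.0
    if single:
        return x[0], converged[0]
    return x, converged


# --------------------------------------------------------------------------
# Triangulation
# --------------------------------------------------------------------------

def triangulate_pair(
    ptA: np.ndarray,
    ptB: np.ndarray,
    rig: StereoRig,
) -> tuple[np.ndarray, float, bool]:
    """Triangulate one correspondence; returns (X in camera-A frame, residual px, degenerate).

    Linear DLT on undistorted normalized observations with projection
    matrices ``[I|0]`` and ``[R|t]``: the homogeneous solution is the right
    singular vector of the 4x4 design matrix with smallest singular value.
    The residual is the RMS of the two reprojection errors in pixels.
    Near-parallel rays (the two smallest singular values within 1e-12)
    yield the degenerate flag.
    """
    xa, okA = undistort_to_normalized(np.asarray(ptA, float), rig.camA)
    xb, okB = undistort_to_normalized(np.asarray(ptB, float), rig.camB)
    if not (okA and okB):
        return np.full(3, np.nan), np.nan, True
    P1 = np.hstack([np.eye(3), np.zeros((3, 1))])
    P2 = np.hstack([rig.R, rig.t.reshape(3, 1)])
    A = np.empty((4, 4))
    A[0] = xa[0] * P1[2] - P1[0]
    A[1] = xa[1] * P1[2] - P1[1]
    A[2] = xb[0] * P2[2] - P2[0]
    A[3] = xb[1] * P2[2] - P2[1]
    _, s, Vt = np.linalg.svd(A)
    if s[2] - s[3] < 1e-12:
        return np.full(3, np.nan), np.nan, True
    Xh = Vt[3]
    if abs(Xh[3]) < 1e-15:
        return np.full(3, np.nan), np.nan, True
    X = Xh[:3] / Xh[3]
    XB = rig.R @ X + rig.t
    if X[2] <= 0 or XB[2] <= 0:
        return np.full(3, np.nan), np.nan, True
    ra = project_to_pixels(X, rig.camA) - np.asarray(ptA, float)
    rb = project_to_pixels(XB, rig.camB) - np.asarray(ptB, float)
    residual = float(np.sqrt((ra @ ra + rb @ rb) / 2.0))
    return X, residual, False


def triangulate_series(
    seriesA: KeypointSeries,
    seriesB: KeypointSeries,
    rig: StereoRig,
) -> SkeletonSeries3D:
    """Triangulate two synchronized keypoint streams into a 3D skeleton.

    A joint is valid at a frame iff it is observed in both cameras and the
    triangulation is non-degenerate.  The result lives in the camera-A
    frame at the cameras' frame rate.
    """
    if seriesA.n_frames != seriesB.n_frames:
        raise ValueError(
            "keypoint series lengths differ "
            f"({seriesA.n_frames} vs {seriesB.n_frames}); "
            "run temporal synchronization first"
        )
    if seriesA.frame_rate != seriesB.frame_rate:
        raise ValueError("keypoint series frame rates differ")
    T = seriesA.n_frames
    xyz = np.zeros((T, N_JOINTS, 3))
    valid = np.zeros((T, N_JOINTS), dtype=bool)
    both = seriesA.valid & seriesB.valid
    for k in range(T):
        for j in np.flatnonzero(both[k]):
            X, _, degenerate = triangulate_pair(
                seriesA.uv[k, j], seriesB.uv[k, j], rig
            )
            if not degenerate:
                xyz[k, j] = X
                valid[k, j] = True
    return SkeletonSeries3D(
        frame_rate=seriesA.frame_rate, xyz=xyz, valid=valid, frame_ref="cameraA"
    )


def reprojection_rms(
    points3D: np.ndarray,
    observationsA: np.ndarray,
    observationsB: np.ndarray,
    rig: StereoRig,
    valid: np.ndarray | None = None,
) -> float:
    """RMS reprojection error (px) of 3D points against both cameras pooled.

    ``points3D`` are in the camera-A frame; observations are pixel pairs
    matched by row.
    """
    X = np.atleast_2d(np.asarray(points3D, float))
    oA = np.atleast_2d(np.asarray(observationsA, float))
    oB = np.atleast_2d(np.asarray(observationsB, float))
    if valid is not None:
        keep = np.asarray(valid, bool)
        X, oA, oB = X[keep], oA[keep], oB[keep]
    if len(X) == 0:
        raise ValueError("reprojection RMS of an empty set is undefined")
    XB = X @ rig.R.T + rig.t
    dA = project_to_pixels(X, rig.camA) - oA
    dB = project_to_pixels(XB, rig.camB) - oB
    sq = np.concatenate([(dA ** 2).sum(axis=1), (dB ** 2).sum(axis=1)])
    return float(np.sqrt(sq.mean()))
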