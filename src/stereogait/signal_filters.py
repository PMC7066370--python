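"""Smoothing operators used by the measurement chain.

Two filters appear in the pipeline:

* a zero-lag 2nd-order Butterworth low-pass (default cut-off 10 Hz) applied
  to every 3D coordinate before any kinematic computation, and
* a zero-phase moving average applied to the ankle-speed signal before the
  hysteresis foot-state detector.

Both are linear, length-preserving, zero-phase (time-reversal symmetric)
and use odd reflection padding at the edges so short gait records remain
usable end to end.

The moving-average default is a symmetric kernel with 24-sample effective
support.  At 30 Hz sampling its transfer function has its first magnitude
zero at 30/24 = 1.25 Hz, placing stride-frequency content (~1 Hz) in the
pass band while strongly attenuating per-step speed oscillations.  A plain
12-tap average (first zero at 2.5 Hz) remains available through the
``window_samples`` parameter.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

DEFAULT_BUTTER_CUTOFF_HZ = 10.0
DEFAULT_SMOOTH_WINDOW = 24


def butter2_zero_phase(
    x: np.ndarray, fs: float, fc: float = DEFAULT_BUTTER_CUTOFF_HZ
) -> np.ndarray:
    """Zero-lag 2nd-order Butterworth low-pass along the first axis.

    Designed by bilinear transform with prewarping and applied forward and
    backward (``filtfilt``), giving zero phase and an effective 4th-order
    magnitude response.  Edges are handled by odd reflection padding of
    length 3 x (order + 1).
    """
    x = np.asarray(x, dtype=float)
    if fc >= fs / 2:
        raise ValueError(f"cut-off {fc} Hz must be below the Nyquist rate {fs / 2} Hz")
    padlen = 3 * (2 + 1)
    if x.shape[0] <= 4 * padlen // 3 or x.shape[0] <= padlen:
        raise ValueError(f"signal too short for zero-phase filtering (need > {padlen} samples)")
    b, a = sps.butter(2, fc, fs=fs)
    return sps.filtfilt(b, a, x, axis=0, padtype="odd", padlen=padlen)


def moving_average_kernel(window_samples: int = DEFAULT_SMOOTH_WINDOW) -> np.ndarray:
    """Symmetric moving-average kernel of the given effective width.

    Odd windows are a plain centered boxcar.  Even windows cannot be
    centered on a sample, so the kernel spans ``window + 1`` taps with
    half-weight endpoints — the convolution of a boxcar with a two-tap
    half-sample shift — keeping the filter symmetric (zero phase) with DC
    gain exactly 1 and the boxcar's spectral zeros intact.
    """
    if window_samples < 1:
        raise ValueError("window must be >= 1")
    w = int(window_samples)
    if w % 2 == 1:
        return np.full(w, 1.0 / w)
    k = np.full(w + 1, 1.0 / w)
    k[0] = k[-1] = 0.5 / w
    return k


def moving_average_transfer(
    freqs_hz: np.ndarray, fs: float, window_samples: int = DEFAULT_SMOOTH_WINDOW
) -> np.ndarray:
    """Real-valued transfer function of the (zero-phase) smoothing kernel.

    Because the kernel is symmetric, its frequency response is purely real:
    ``H(f) = w0 + 2 sum_m w_m cos(2 pi f m / fs)``.  Zeros of the magnitude
    are sign changes of this function.
    """
    k = moving_average_kernel(window_samples)
    half = len(k) // 2
    m = np.arange(1, half + 1)
    f = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
    H = k[half] + 2.0 * (k[half + m][None, :] *
                         np.cos(2 * np.pi * f[:, None] * m[None, :] / fs)).sum(axis=1)
    return H if np.ndim(freqs_hz) else H[0]


def first_transfer_zero_hz(
    fs: float,
    window_samples: int = DEFAULT_SMOOTH_WINDOW,
    grid_points: int = 30000,
    tol: float = 1e-9,
) -> float:
    """Lowest frequency (Hz) at which the smoother's magnitude response is zero.

    Scans a dense grid over (0, fs/2], brackets the first sign change of
    the real transfer function and refines it by bisection to *tol*.
    """
    from scipy.optimize import brentq

    f = np.linspace(0.0, fs / 2, grid_points + 1)[1:]
    H = moving_average_transfer(f, fs, window_samples)
    exact = np.flatnonzero(np.abs(H) < tol)
    sign_change = np.flatnonzero(np.sign(H[:-1]) != np.sign(H[1:]))
    if exact.size and (not sign_change.size or exact[0] <= sign_change[0]):
        return float(f[exact[0]])
    if not sign_change.size:
        raise ValueError("no transfer-function zero below the Nyquist rate")
    i = sign_change[0]
    root = brentq(
        lambda fr: moving_average_transfer(fr, fs, window_samples),
        f[i], f[i + 1], xtol=tol,
    )
    return float(root)


def moving_average_smooth(
    x: np.ndarray, window_samples: int = DEFAULT_SMOOTH_WINDOW
) -> np.ndarray:
    """Zero-phase moving average along the first axis with odd-reflection edges."""
    x = np.asarray(x, dtype=float)
    k = moving_average_kernel(window_samples)
    half = len(k) // 2
    n = x.shape[0]
    if window_samples > n:
        raise ValueError("window longer than signal")
    pad = min(half, n - 1)
    # odd (antisymmetric) reflection about the end samples
    head = 2 * x[:1] - x[1:pad + 1][::-1]
    tail = 2 * x[-1:] - x[-pad - 1:-1][::-1]
    ext = np.concatenate([head, x, tail], axis=0)
    if pad < half:  # very short signal: extend linearly
        extra = half - pad
        slope0 = ext[1] - ext[0]
        slope1 = ext[-1] - ext[-2]
        head2 = ext[0] - slope0 * np.arange(extra, 0, -1)[:, None] if x.ndim > 1 \
            else ext[0] - slope0 * np.arange(extra, 0, -1)
        tail2 = ext[-1] + slope1 * np.arange(1, extra + 1)[:, None] if x.ndim > 1 \
            else ext[-1] + slope1 * np.arange(1, extra + 1)
        ext = np.concatenate([head2, ext, tail2], axis=0)
    if x.ndim == 1:
        return np.convolve(ext, k, mode="valid")
    out = np.empty_like(x)
    for c in range(x.shape[1]):
        out[:, c] = np.convolve(ext[:, c], k, mode="valid")
    return out
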