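"""Gait event detection and spatio-temporal parameter extraction.

The foot state (stance = 0, swing = 1) is read off the speed of the ankle
joint: during stance the foot is planted and the ankle is nearly still;
during swing it moves fast.  The detector is a two-threshold hysteresis
automaton on the smoothed ankle-speed signal:

* ``HystHighSpeed`` — switches stance -> swing when exceeded; set per
  recording to the nearest-rank 65th percentile of the sorted valid
  smoothed speeds.
* ``HystLowSpeed`` — switches swing -> stance when undercut; fixed at 80%
  of the high threshold so residual noise near the boundary cannot chatter
  the state.

Heel strike is the swing -> stance transition, toe off the stance -> swing
transition.  Only complete step cycles are measured: the four possible
combinations of entry/exit state of the recording window decide which
boundary cycles are discarded.  From the surviving events come the three
headline parameters: step length (ground-plane distance between a heel
strike and the opposite foot's immediately preceding heel strike), stance
time and swing time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import COCO18_INDEX
from .signal_filters import DEFAULT_SMOOTH_WINDOW, moving_average_smooth
from .stereo_geometry import SkeletonSeries3D

HYSTERESIS_RATIO = 0.8       # low threshold = 0.8 x high threshold
SPEED_PERCENTILE = 0.65      # nearest-rank percentile for the high threshold

_ANKLE = {"left": COCO18_INDEX["LAnkle"], "right": COCO18_INDEX["RAnkle"]}


@dataclass
class SpeedSeries:
    """Per-frame ankle speed magnitude (m/s) for one foot."""

    foot: str                 # "left" | "right"
    frame_rate: float
    v: np.ndarray             # (T,) m/s
    valid: np.ndarray         # (T,) bool

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if np.any(self.v[self.valid] < 0):
            raise ValueError("speeds must be non-negative where valid")


@dataclass
class HysteresisThresholds:
    """The pair of switching speeds of the foot-state automaton (m/s)."""

    high: float
    low: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError("thresholds must satisfy 0 < low < high")
        if abs(self.low - HYSTERESIS_RATIO * self.high) > 1e-12:
            raise ValueError("low must equal 0.8 x high")


@dataclass
class FootStateSeries:
    """Per-frame stance(0)/swing(1) labels for one foot."""

    foot: str
    frame_rate: float
    states: np.ndarray        # (T,) int in {0, 1}

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)
        if not np.isin(self.states, (0, 1)).all():
            raise ValueError("states must be 0 (stance) or 1 (swing)")


@dataclass
class StepRecord:
    """One gait step: timing and length of a single foot placement."""

    foot: str
    heel_strike_time: float
    heel_strike_position: np.ndarray | None
    step_length: float | None       # m, to previous opposite-foot heel strike
    stance_time: float | None       # s
    swing_time: float | None        # s
    complete: bool = True
    stride_length: float | None = None  # m, to previous same-foot heel strike

    def __post_init__(self) -> None:
        if self.stance_time is not None and self.stance_time <= 0:
            raise ValueError("stance_time must be positive")
        if self.swing_time is not None and self.swing_time <= 0:
            raise ValueError("swing_time must be positive")
        if self.step_length is not None and self.step_length < 0:
            raise ValueError("step_length must be non-negative")


# --------------------------------------------------------------------------
# Gap handling and speed computation
# --------------------------------------------------------------------------

def interpolate_short_gaps(series: SkeletonSeries3D, max_gap: int = 5) -> SkeletonSeries3D:
    """Linearly fill invalid runs of <= *max_gap* frames per joint.

    Longer gaps stay invalid; filled frames become valid.  Applied before
    low-pass filtering so the filters see contiguous signals.
    """
    out = series.copy()
    T = series.n_frames
    for j in range(series.xyz.shape[1]):
        ok = series.valid[:, j]
        if ok.all() or ok.sum() < 2:
            continue
        idx = np.flatnonzero(~ok)
        # contiguous runs of invalid frames
        splits = np.flatnonzero(np.diff(idx) > 1) + 1
        for run in np.split(idx, splits):
            a, b = run[0] - 1, run[-1] + 1  # enclosing valid frames
            if a < 0 or b >= T or len(run) > max_gap:
                continue
            if not (ok[a] and ok[b]):
                continue
            w = (run - a) / (b - a)
            out.xyz[run, j, :] = (
                (1 - w)[:, None] * series.xyz[a, j, :]
                + w[:, None] * series.xyz[b, j, :]
            )
            out.valid[run, j] = True
    return out


def ankle_speed(series: SkeletonSeries3D, foot: str) -> SpeedSeries:
    """Speed magnitude of one ankle: ``v_i = f * ||p_i - p_{i-1}||``.

    The first sample repeats the second so the series keeps the input
    length.  Frames adjacent to an invalid position are invalid.  Input
    positions should already be low-pass filtered (10 Hz Butterworth).
    """
    j = _ANKLE[foot]
    p = series.xyz[:, j, :]
    ok = series.valid[:, j]
    if ok.sum() < 2:
        raise ValueError(f"{foot} ankle valid in fewer than 2 frames")
    f = series.frame_rate
    v = np.zeros(len(p))
    v[1:] = f * np.linalg.norm(np.diff(p, axis=0), axis=1)
    valid = np.zeros(len(p), dtype=bool)
    valid[1:] = ok[1:] & ok[:-1]
    if len(v) > 1:
        v[0] = v[1]
        valid[0] = valid[1]
    v[~valid] = 0.0
    return SpeedSeries(foot=foot, frame_rate=f, v=v, valid=valid)


def smooth_speed(speed: SpeedSeries,
                 window_samples: int = DEFAULT_SMOOTH_WINDOW) -> SpeedSeries:
    """Zero-phase moving-average smoothing of a speed series."""
    v = moving_average_smooth(speed.v, window_samples)
    return SpeedSeries(speed.foot, speed.frame_rate,
                       np.maximum(v, 0.0), speed.valid.copy())


# --------------------------------------------------------------------------
# Thresholds and the hysteresis automaton
# --------------------------------------------------------------------------

def crop_to_active(speed: SpeedSeries, frac: float = 0.2) -> SpeedSeries:
    """Restrict a speed series to its active gait span for calibration.

    A recording may contain standing phases (the synchronization-gesture
    prologue, a standing tail) whose near-zero speeds dilute the percentile
    the threshold estimator relies on.  The active span runs from the first
    to the last sample exceeding ``frac`` of the 95th-percentile speed;
    samples outside it are marked invalid, values untouched.
    """
    v, ok = speed.v, speed.valid
    if not ok.any():
        return speed
    level = frac * np.percentile(v[ok], 95)
    big = np.flatnonzero(ok & (v > level))
    if big.size == 0:
        return speed
    inside = np.zeros(len(v), dtype=bool)
    inside[big[0]:big[-1] + 1] = True
    return SpeedSeries(speed.foot, speed.frame_rate, v.copy(), ok & inside)


def estimate_thresholds(calibration_speed: SpeedSeries) -> HysteresisThresholds:
    """Per-recording hysteresis thresholds from the smoothed speed histogram.

    Sorts all valid smoothed speeds ascending and takes the nearest-rank
    65th percentile (1-based index ``ceil(0.65 n)``) as the high threshold;
    the low threshold is 80% of it.
    """
    v = calibration_speed.v[calibration_speed.valid]
    n = v.size
    if n < 20:
        raise ValueError(f"need >= 20 valid speed samples, got {n}")
    if np.ptp(v) < 1e-12:
        raise ValueError("no gait dynamics in calibration record (flat speeds)")
    v_sorted = np.sort(v)
    rank = int(np.ceil(SPEED_PERCENTILE * n))  # 1-based nearest rank
    high = float(v_sorted[rank - 1])
    if high <= 0:
        raise ValueError("65th-percentile speed is zero; no gait dynamics")
    return HysteresisThresholds(high=high, low=HYSTERESIS_RATIO * high)


def detect_foot_states(
    speed: SpeedSeries, th: HysteresisThresholds
) -> FootStateSeries:
    """Run the two-threshold automaton over a smoothed speed series.

    In time order: state -> swing when ``v > high``; state -> stance when
    ``v < low``; otherwise (the hysteresis band) the state is held.  The
    initial state compares ``v_0`` against the high threshold; invalid
    frames inherit the previous state.
    """
    v, ok = speed.v, speed.valid
    states = np.zeros(len(v), dtype=int)
    first = np.flatnonzero(ok)
    state = 0
    if first.size and v[first[0]] > th.high:
        state = 1
    for k in range(len(v)):
        if ok[k]:
            if v[k] > th.high:
                state = 1
            elif v[k] < th.low:
                state = 0
        states[k] = state
    return FootStateSeries(speed.foot, speed.frame_rate, states)


# --------------------------------------------------------------------------
# Events, trimming and parameters
# --------------------------------------------------------------------------

def _transitions(states: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(heel-strike frames, toe-off frames): 1->0 and 0->1 transitions."""
    d = np.diff(states)
    heel = np.flatnonzero(d == -1) + 1
    toe = np.flatnonzero(d == 1) + 1
    return heel, toe


def trim_incomplete(states: FootStateSeries) -> tuple[list[tuple[int, int]], int]:
    """Select complete step cycles from the recording window.

    Complete cycles are delimited by consecutive heel strikes of the foot;
    a step truncated by the window boundary is never bounded by two heel
    strikes, so the enumeration excludes exactly the partial steps the
    four boundary cases prescribe dropping:

    1. enter swing, exit swing  -> first and last (partial) steps dropped;
    2. enter stance, exit swing -> last (partial) step dropped;
    3. enter swing, exit stance -> first (partial) step dropped;
    4. enter stance, exit stance -> every step is complete and kept.

    Returns ``(list of (start, end) heel-strike frame pairs, case)``; an
    empty list (not an error) when no complete cycle exists.
    """
    s = states.states
    heel, _ = _transitions(s)
    enter, exit_ = int(s[0]), int(s[-1])
    case = {(1, 1): 1, (0, 1): 2, (1, 0): 3, (0, 0): 4}[(enter, exit_)]
    cycles = [(int(heel[i]), int(heel[i + 1])) for i in range(len(heel) - 1)]
    return cycles, case


def _ground_plane(p: np.ndarray) -> np.ndarray:
    """Project a lab-frame position onto the ground plane (drop vertical z)."""
    return p[..., :2]


def compute_parameters(
    statesL: FootStateSeries,
    statesR: FootStateSeries,
    skeleton: SkeletonSeries3D,
) -> list[StepRecord]:
    """Extract per-step spatio-temporal parameters from both feet's states.

    For each complete cycle of a foot (consecutive heel strikes surviving
    :func:`trim_incomplete`):

    * stance time  = toe off - heel strike (same foot);
    * swing time   = next heel strike - toe off;
    * step length  = ground-plane distance between the ankle position at
      the cycle's closing heel strike and the opposite ankle position at
      its immediately preceding heel strike (the clinical step, opposite
      feet); the stride length (same foot) is kept as a derived field.

    The skeleton must be in the laboratory frame (vertical = z) and
    Butterworth-filtered; heel-strike positions are read from the filtered
    ankle trajectory at the event frame.
    """
    if skeleton.frame_rate != statesL.frame_rate:
        raise ValueError("states and skeleton frame rates differ")
    f = skeleton.frame_rate
    heel = {}
    toe = {}
    cycles = {}
    for st in (statesL, statesR):
        h, t = _transitions(st.states)
        heel[st.foot], toe[st.foot] = h, t
        cycles[st.foot], _ = trim_incomplete(st)
    if len(heel["left"]) + len(heel["right"]) >= 3:
        merged = sorted(
            [(k, "left") for k in heel["left"]] + [(k, "right") for k in heel["right"]]
        )
        feet_order = [foot for _, foot in merged]
        if all(a == b for a, b in zip(feet_order, feet_order[1:])):
            raise ValueError(
                "single-support sequence implausible: left and right heel "
                "strikes never interleave"
            )
    records: list[StepRecord] = []
    for foot, other in (("left", "right"), ("right", "left")):
        j = _ANKLE[foot]
        jo = _ANKLE[other]
        for start, end in cycles[foot]:
            toes = toe[foot][(toe[foot] > start) & (toe[foot] < end)]
            if toes.size != 1:
                continue  # malformed cycle (extra chatter): skip
            toe_k = int(toes[0])
            stance_time = (toe_k - start) / f
            swing_time = (end - toe_k) / f
            hs_pos = skeleton.xyz[end, j, :] if skeleton.valid[end, j] else None
            # previous opposite-foot heel strike before this cycle's close
            prev_opp = heel[other][heel[other] < end]
            step_length = None
            if hs_pos is not None and prev_opp.size:
                ko = int(prev_opp[-1])
                if skeleton.valid[ko, jo]:
                    step_length = float(np.linalg.norm(
                        _ground_plane(hs_pos) - _ground_plane(skeleton.xyz[ko, jo, :])
                    ))
            stride_length = None
            if hs_pos is not None and skeleton.valid[start, j]:
                stride_length = float(np.linalg.norm(
                    _ground_plane(hs_pos) - _ground_plane(skeleton.xyz[start, j, :])
                ))
            records.append(StepRecord(
                foot=foot,
                heel_strike_time=end / f,
                heel_strike_position=None if hs_pos is None else hs_pos.copy(),
                step_length=step_length,
                stance_time=stance_time,
                swing_time=swing_time,
                complete=True,
                stride_length=stride_length,
            ))
    records.sort(key=lambda r: r.heel_strike_time)
    return records
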