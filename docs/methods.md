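# Methods

This note documents the models, numerical choices and known limitations of
the `stereogait` measurement chain and of the synthetic laboratory used to
validate it.

## Camera model and triangulation

Each webcam is a pinhole camera with Brown–Conrady distortion: a point
`(x, y, z)` in the camera frame (z forward, x right, y down) maps to
normalized coordinates `x' = x/z, y' = y/z`, is warped radially by
`1 + k1 r² + k2 r⁴ + k3 r⁶` and tangentially by `(p1, p2)`, and is scaled
to pixels by the focal lengths and principal point. Undistortion inverts
this by fixed-point iteration (tolerance 1e-10, at most 50 iterations);
non-converging points are flagged invalid rather than raising, since a
single wild keypoint must not abort a recording.

Two-view reconstruction uses the linear DLT formulation on undistorted
normalized observations with projection matrices `[I|0]` and `[R|t]`
(`X_B = R·X_A + t` between camera frames): the homogeneous solution is the
right singular vector with smallest singular value of the 4×4 design
matrix. Degeneracy (near-parallel rays) is declared when the two smallest
singular values agree within 1e-12. The midpoint and polynomial-optimal
variants were deliberately not used: DLT is the generic "functional
triangulation" of standard calibration toolboxes and is exactly testable —
on noise-free synthetic projections the round trip is below 1e-6 m over
the full 3×2×2 m working volume, and this exactness is asserted in the
suite.

Reprojection RMS pools the per-point Euclidean pixel errors of both
cameras. With isotropic per-axis noise σ on exact points this statistic
equals σ·√2 (not σ), which the Monte-Carlo test asserts.

## Synchronization

The wrist-to-hip tap gesture gives both systems a common scalar signal:
the 3D distance between the right wrist and right hip joint centers
(computed on the triangulated series for the cameras; whether the original
protocol used 2D or 3D distances for the webcams is not documented — 3D is
the natural choice once triangulation precedes synchronization). The
reference is downsampled from 100 to 30 Hz by cubic splines; a resampled
sample is valid only when both enclosing source samples are. The integer
lag (at 30 Hz) maximizing the normalized cross-correlation of the
mean-removed signals over their valid overlap aligns the streams; ties
break toward the smallest |lag|. Sub-frame refinement is intentionally
absent: all downstream tolerances are one 30 Hz frame or coarser, and
clock drift over recordings of a few seconds is far below a frame.

Two pipeline defaults (overridable in `PipelineSettings`) make the
correlation robust under heavy keypoint noise: gesture signals are
smoothed with a 0.2 s zero-phase moving average before correlating, and
the lag search is bounded to ±2 s — both measurement systems are started
by an operator within moments of each other, so wider lags are spurious
by construction. With the default search width, normalized correlation on
short accidental overlaps can otherwise outscore the true alignment.

## Rigid alignment

Both the lab alignment and the evaluation alignment use the Kabsch
solution: SVD of the centered cross-covariance, rotation
`V·diag(1,1,d)·Uᵀ` with `d = sign(det(V·Uᵀ))` so reflections are
impossible, translation from the centroids. One global transform per
recording is estimated from all valid (frame × node) correspondences
stacked as a single point set; correspondences with either side invalid
are dropped, never imputed. Per-frame alignment would absorb genuine
measurement error and was rejected.

The 13 evaluation nodes are the skeletal landmarks shared by the two
systems: sternum (the neck keypoint) plus shoulders, elbows, wrists, hips,
knees and ankles by side. Face keypoints have no marker counterpart and
never enter alignment or evaluation.

## Filters

- Coordinates: zero-lag 2nd-order Butterworth, cut-off 10 Hz, applied
  forward and backward (`filtfilt`, odd reflection padding of length
  3×(order+1) = 9). Valid runs shorter than 14 samples pass through
  unfiltered rather than raising. The forward–backward pass squares the
  magnitude response, so the gain at the cut-off is 0.5.
- Ankle speed: a zero-phase moving average. The default kernel has an
  effective 24-sample support (even windows are realized as a symmetric
  `window+1`-tap kernel with half-weight endpoints, preserving DC gain 1
  and the boxcar's spectral zeros), so at 30 Hz its first
  transfer-function zero falls at 30/24 = 1.25 Hz — below the step
  frequency of comfortable walking, above stride frequency. A plain
  12-tap average (first zero 2.5 Hz) is available through the
  `window_samples` parameter; the 24-sample default is the reading
  consistent with the 1.25 Hz spectral anchor, and that anchor is the
  quantity `scripts/acceptance.py` recomputes.

Missing joint positions in runs of at most 5 frames are filled by linear
interpolation before filtering; longer gaps stay invalid and invalidate
overlapping speed samples and gait cycles.

## Gait events and parameters

Ankle speed is `v_i = f·‖p_i − p_{i−1}‖` on the Butterworth-filtered 3D
trajectory (`v_0` repeats `v_1`). The foot-state automaton scans the
smoothed speed in time order: swing (1) when `v` exceeds `HystHighSpeed`,
stance (0) when it drops below `HystLowSpeed`, previous state held inside
the band; invalid frames inherit the previous state. The initial state
compares the first sample against the high threshold — the four-case
boundary trimming makes this choice immaterial for complete cycles.

Thresholds are calibrated per recording and per foot: the high threshold
is the nearest-rank 65th percentile (1-based index ⌈0.65·n⌉ of the
ascending sort) of the valid smoothed speeds, the low threshold is exactly
80% of it. Because our recordings contain a standing tap prologue whose
near-zero speeds would dilute the percentile, calibration first crops the
speed series to its active gait span (first to last exceedance of 20% of
the 95th-percentile speed). Recordings with flat speed are rejected as
containing no gait.

Complete cycles are delimited by consecutive same-foot heel strikes
(swing→stance transitions); steps truncated by the window boundary are
never bounded by two heel strikes and so are excluded automatically, which
realizes the four entry/exit boundary cases (the case number is reported).
Per cycle: stance time = toe off − heel strike, swing time = next heel
strike − toe off, step length = ground-plane Euclidean distance between
the ankle at the cycle's closing heel strike and the opposite ankle at its
immediately preceding heel strike (the clinical step; stride length is
kept as a derived field). Heel-strike positions are read from the filtered
ankle trajectory and projected to the ground plane, removing vertical
noise from a planar quantity.

### Known systematic bias of event timing

With a symmetric (zero-phase) smoother and a symmetric swing-speed pulse,
the rising crossing of the high threshold and the falling crossing of the
low threshold cannot both coincide with the true events unless the two
thresholds were equal; the measured swing is therefore longer than truth
by the high-to-low fall time of the smoothed speed (and stance shorter by
the same amount). Under the simulator's smooth swing profile this bias is
2–4 frames at 30 Hz depending on cadence and stance fraction, and no
percentile or calibration-crop choice removes it. Crucially, both
measurement systems share the bias, so it cancels in the markerless-vs-
reference comparison — system agreement on stance/swing is within one
frame on noise-free data — but absolute stance/swing durations should be
interpreted with this offset in mind. Step length is unaffected: the ankle
is stationary throughout stance, so the heel-strike position is
insensitive to the timing offset, and noise-free step-length recovery is
exact to well under 1 cm.

## Evaluation

Node RMS: per node, the RMS over valid frames of the 3D distance after
the single optimal rigid alignment, reported in mm (the customary unit);
nodes with no valid overlap are absent, not zero. The report's mean and SD
are over the 13 node values. All synchronized frames enter the RMS (no
gait-cycle cropping).

Steps are paired per foot by greedy nearest heel-strike time within
0.25 s — an artifact convention; the original protocol's pairing rule is
not documented. Parameter RMS errors are over paired differences
(step length in cm, times in s). Bland–Altman: bias = mean(markerless −
reference), limits = bias ± 1.96·sample SD, requiring at least 3 pairs.

The factorial ANOVA regresses an error measure on ±1-coded gait direction
(x1), camera distance (x2) and resolution (x3) plus the x1·x2 interaction
by ordinary least squares (statsmodels); each effect gets a partial F test
(the squared t statistic) against F(1, residual dof) at α = 0.05. Under
the balanced design the coding is orthogonal, so Type I and Type III sums
of squares coincide; subject is not a factor (recordings pool across
subjects). Degenerate inputs — empty design cells, no residual degrees of
freedom, uncoded levels — raise rather than silently misreport; an exactly
constant response reports F = 0, p = 1. Calibration is asserted by
simulation: the null rejection rate at α = 0.05 stays within [0.03, 0.07]
over 2000 draws, and a single-factor effect twice the noise SD is detected
with power above 0.95.

## The synthetic laboratory

The avatar is kinematic, not dynamic. Per stride: the stance ankle is
exactly stationary; the swing ankle advances two step lengths along the
path with profile `s(τ) = 2L·(τ − sin(2πτ)/(2π))` and vertical lift
`0.05·sin(πτ)` m over the swing duration `(1 − stance_fraction)·stride`.
Both ankles travel on the path line (zero step width), so every true step
length equals the configured value exactly — the bookkeeping the recovery
tests depend on. The pelvis rides at the ankles' mean path coordinate with
a 2 cm vertical sinusoid at stride frequency; hips sit ±10 cm laterally;
knees interpolate 45/55 between hip and ankle with a 3 cm forward bump
mid-swing; shoulders hang 0.30·height above the hips; arms swing ±20°
anti-phase; the face rides fixed offsets from the neck. Segment lengths
scale with subject height (leg 0.53·H, trunk 0.30·H); the two default
subjects are 1.73 m and 1.82 m. In the prologue the right hand is held
raised before the hip and beaten against it at each tap — a deliberately
large (~0.3 m) gesture so the synchronization signal survives heavy
keypoint noise, as the real gesture does.

Scene defaults are the study conditions: cameras on a bar at 2.3 m height
with baseline 1.0 or 1.8 m, auto-pitched so the mid-path point projects to
the image center; native full-HD intrinsics (f = 1400 px, mild
distortion) scaled to 1312×736 (HR) or 640×480 (LR); the path ends 2.2 m
from the camera bar so the subject spans roughly 2–6 m from the cameras;
recordings collect 5 steps by default (4–5 steps in a few seconds is the
realistic laboratory pass). Resolution is modeled by scaling intrinsics,
never by image resampling — the artifact never touches pixels.

Keypoint noise is Gaussian with σ = 2 px in rendered-image pixels
(a realistic magnitude for CNN pose estimators), identical at both
resolutions, so the lower resolution carries proportionally larger
normalized — hence 3D — error, which is the mechanism behind the
resolution effect. Occlusion in diagonal walking is modeled statistically,
not by ray casting: far-side joints receive extra Gaussian noise (default
4 px) on top of dropout, reproducing the error structure of a pose network
guessing hidden landmarks at a fraction of the complexity. Keypoints drop
out (confidence 0) with probability 0.02; kept confidences are U(0.4, 1).
The reference renderer adds isotropic σ = 0.2 mm, the marker-location
reconstruction error of laboratory optoelectronic systems. The markerless
clock starts a configurable integer number of frames late (default 3).
Every output is a pure function of the configurations and the seed.

What the simulator does **not** emulate: soft-tissue artifact, true
self-occlusion geometry, pose-network failure modes (left/right swaps,
person mis-detection), rolling shutter, lens-model mismatch, and
non-steady gait. Passing tests therefore demonstrate the correctness of
the measurement chain under a controlled error model, not the field
accuracy of any particular pose network.

## Problem sizes used in the test suite

Geometric oracles sweep 1000 random points; Monte-Carlo noise checks use
300–1000 draws; gait recovery runs six noise-free configurations of 8
steps spanning straight and both diagonal directions; ANOVA calibration
uses 2000 null simulations and 200 power simulations; the factorial-
ordering check runs the full 8-cell design with one replicate and both
subjects (16 end-to-end recordings). These sizes give comfortable
statistical margins for every asserted property while keeping the default
suite fast.

## Known limitations

- Stance/swing absolute bias of the hysteresis detector (discussed above).
- Under the harshest synthetic condition (low resolution, 1.0 m baseline,
  diagonal path) the speed signal can be too noisy for reliable step
  extraction; the pipeline then reports the gait parameters as absent for
  that recording while the trajectory comparison still stands.
- Single walker only; multi-person scenes must be resolved upstream by the
  person-selection policy of the keypoint reader.
- Exactly two cameras; no bundle adjustment or multi-view fusion.
- Calibration is consumed, never estimated: the stereo rig file must come
  from an external calibration procedure.
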