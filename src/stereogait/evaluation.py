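"""Metrological comparison of the markerless output against the reference.

Four instruments quantify agreement between the two measurement systems:

* **Node RMS** — after one optimal rigid roto-translation (Kabsch over all
  stacked frame x node correspondences) the per-node root-mean-square 3D
  distance between the trajectories of the 13 evaluation nodes, in mm.
* **Parameter RMS error** — per-step differences in step length, stance
  time and swing time over time-matched step pairs.
* **Bland–Altman** — bias (mean difference) and 1.96 SD limits of
  agreement per gait parameter.
* **Two-level factorial ANOVA** — ordinary least squares of an error
  measure on the three +-1-coded design factors (gait direction, camera
  distance, resolution) and the direction x distance interaction, with
  per-effect F tests at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .gait_events import StepRecord
from .io_formats import DEFAULT_NODE_MAP, TrajectoryTable
from .stereo_geometry import SkeletonSeries3D
from .sync_align import RigidTransform, _stack_correspondences, apply_transform, kabsch

ALPHA = 0.05
STEP_MATCH_TOLERANCE_S = 0.25


@dataclass
class NodeErrorReport:
    """Per-node RMS trajectory distance (mm) after rigid alignment."""

    node_rms_mm: dict[str, float]
    mean_mm: float
    sd_mm: float
    transform: RigidTransform | None = None

    def as_series(self) -> pd.Series:
        return pd.Series(self.node_rms_mm, name="rms_mm")


@dataclass
class ParamErrorReport:
    """RMS error per gait parameter over matched step pairs."""

    rms: dict[str, float]     # step_length_cm, stance_time_s, swing_time_s
    n_matched: dict[str, int]


@dataclass
class BlandAltmanStats:
    """Agreement statistics of one parameter between the two systems."""

    parameter: str
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    n: int


@dataclass
class AnovaTable:
    """Factorial ANOVA of one error measure on the design factors."""

    dependent: str
    intercept: float
    effects: pd.DataFrame   # rows: effect; columns: coefficient, F, p, significant
    residual_var: float
    residual_dof: int


# --------------------------------------------------------------------------
# Trajectory agreement
# --------------------------------------------------------------------------

def align_for_comparison(
    op: SkeletonSeries3D,
    ref: TrajectoryTable,
    node_map: dict[str, int] | None = None,
) -> tuple[SkeletonSeries3D, RigidTransform]:
    """Optimal single rigid alignment of the markerless series onto the reference.

    All valid (frame x mapped node) correspondences are stacked into one
    Kabsch problem; the resulting roto-translation is applied to the whole
    markerless series.  The skeletal structures of the two systems are not
    identical, so a residual offset remains by construction — exactly what
    the node RMS then measures.
    """
    P, Q = _stack_correspondences(op, ref, node_map)
    T = kabsch(P, Q, from_frame=op.frame_ref, to_frame=ref.frame_ref)
    return apply_transform(op, T), T


def node_rms(
    aligned_op: SkeletonSeries3D,
    ref: TrajectoryTable,
    node_map: dict[str, int] | None = None,
    transform: RigidTransform | None = None,
) -> NodeErrorReport:
    """Per-node RMS 3D distance (mm) between aligned trajectories.

    Frames invalid in either system are excluded per node; a node with no
    valid frame is absent from the report rather than reported as zero.
    """
    node_map = DEFAULT_NODE_MAP if node_map is None else node_map
    out: dict[str, float] = {}
    for name, op_idx in node_map.items():
        ref_idx = ref.joint_index(name)
        ok = aligned_op.valid[:, op_idx] & ref.valid[:, ref_idx]
        if not ok.any():
            continue
        d2 = ((aligned_op.xyz[ok, op_idx, :] - ref.xyz[ok, ref_idx, :]) ** 2).sum(axis=1)
        out[name] = float(np.sqrt(d2.mean()) * 1000.0)
    if not out:
        raise ValueError("no node has any valid overlapping frame")
    vals = np.array(list(out.values()))
    return NodeErrorReport(
        node_rms_mm=out,
        mean_mm=float(vals.mean()),
        sd_mm=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        transform=transform,
    )


# --------------------------------------------------------------------------
# Step matching and parameter agreement
# --------------------------------------------------------------------------

def match_steps(
    op_steps: list[StepRecord],
    ref_steps: list[StepRecord],
    tolerance_s: float = STEP_MATCH_TOLERANCE_S,
) -> tuple[list[tuple[StepRecord, StepRecord]], list[StepRecord], list[StepRecord]]:
    """Greedy nearest-heel-strike-time pairing of step records, per foot.

    Pairs within *tolerance_s* are matched closest-first; returns
    ``(pairs, unmatched_op, unmatched_ref)``.
    """
    pairs: list[tuple[StepRecord, StepRecord]] = []
    unmatched_op: list[StepRecord] = []
    unmatched_ref: list[StepRecord] = []
    for foot in ("left", "right"):
        ops = [s for s in op_steps if s.foot == foot]
        refs = [s for s in ref_steps if s.foot == foot]
        candidates = sorted(
            (
                (abs(o.heel_strike_time - r.heel_strike_time), i, j)
                for i, o in enumerate(ops)
                for j, r in enumerate(refs)
            ),
        )
        used_o: set[int] = set()
        used_r: set[int] = set()
        for dt, i, j in candidates:
            if dt > tolerance_s or i in used_o or j in used_r:
                continue
            pairs.append((ops[i], refs[j]))
            used_o.add(i)
            used_r.add(j)
        unmatched_op += [o for i, o in enumerate(ops) if i not in used_o]
        unmatched_ref += [r for j, r in enumerate(refs) if j not in used_r]
    pairs.sort(key=lambda p: p[1].heel_strike_time)
    return pairs, unmatched_op, unmatched_ref


_PARAM_GETTERS = {
    "step_length": lambda s: s.step_length,
    "stance_time": lambda s: s.stance_time,
    "swing_time": lambda s: s.swing_time,
}


def _paired_differences(pairs, parameter: str) -> np.ndarray:
    get = _PARAM_GETTERS[parameter]
    d = [
        get(o) - get(r)
        for o, r in pairs
        if get(o) is not None and get(r) is not None
    ]
    return np.asarray(d, dtype=float)


def param_errors(pairs) -> ParamErrorReport:
    """RMS of per-pair differences for the three gait parameters.

    Step-length RMS is reported in cm, times in s, mirroring the field's
    customary units.
    """
    rms: dict[str, float] = {}
    n: dict[str, int] = {}
    for parameter in _PARAM_GETTERS:
        d = _paired_differences(pairs, parameter)
        if d.size == 0:
            continue
        value = float(np.sqrt((d ** 2).mean()))
        if parameter == "step_length":
            rms["step_length_cm"] = value * 100.0
            n["step_length_cm"] = d.size
        else:
            rms[f"{parameter}_s"] = value
            n[f"{parameter}_s"] = d.size
    if not rms:
        raise ValueError("no matched pair carries any comparable parameter")
    return ParamErrorReport(rms=rms, n_matched=n)


def bland_altman(pairs, parameter: str) -> BlandAltmanStats:
    """Bland–Altman agreement of one parameter: bias and 1.96 SD limits.

    Differences are markerless minus reference, so a negative bias means
    the markerless system underestimates.
    """
    d = _paired_differences(pairs, parameter)
    if d.size < 3:
        raise ValueError("Bland–Altman needs >= 3 matched pairs with values")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanStats(
        parameter=parameter, bias=bias, sd=sd,
        loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd, n=d.size,
    )


# --------------------------------------------------------------------------
# Factorial ANOVA
# --------------------------------------------------------------------------

_EFFECTS = ("x1", "x2", "x3", "x1:x2")
EFFECT_LABELS = {
    "x1": "gait_direction",
    "x2": "camera_distance",
    "x3": "resolution",
    "x1:x2": "direction_x_distance",
}


def factorial_anova(error_table: pd.DataFrame, dependent: str = "value") -> AnovaTable:
    """Two-level factorial ANOVA of an error measure on the design factors.

    *error_table* must carry +-1-coded columns ``x1`` (gait direction),
    ``x2`` (camera distance), ``x3`` (resolution) and the response column
    named by *dependent*.  The model is ordinary least squares on the
    intercept, the three main effects and the x1*x2 interaction; each
    effect gets a partial F test with (1, residual dof) degrees of freedom
    (equivalently the squared t statistic), flagged at alpha = 0.05.
    Under the balanced design the coding makes effects orthogonal, so
    Type I and Type III sums of squares coincide.
    """
    for col in ("x1", "x2", "x3", dependent):
        if col not in error_table.columns:
            raise ValueError(f"error table lacks column {col!r}")
    levels = error_table[["x1", "x2", "x3"]].to_numpy(dtype=float)
    if not np.isin(levels, (-1.0, 1.0)).all():
        raise ValueError("factor levels must be coded -1/+1")
    y = error_table[dependent].to_numpy(dtype=float)
    X = np.column_stack([
        np.ones(len(y)),
        levels[:, 0], levels[:, 1], levels[:, 2],
        levels[:, 0] * levels[:, 1],
    ])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design: some factor combinations are empty")
    if len(y) <= X.shape[1]:
        raise ValueError("not enough replicates for residual degrees of freedom")
    fit = sm.OLS(y, X).fit()
    dof = int(fit.df_resid)
    resid_var = float(fit.ssr / dof)
    tiny = 1e-20 * max(1.0, float(np.abs(y).max()) ** 2)
    rows = []
    for i, eff in enumerate(_EFFECTS, start=1):
        beta = float(fit.params[i])
        if resid_var > tiny:
            F = float(fit.tvalues[i] ** 2)
            p = float(stats.f.sf(F, 1, dof))
        else:  # perfectly constant response
            F, p = 0.0, 1.0
        rows.append({
            "effect": EFFECT_LABELS[eff], "coefficient": beta,
            "F": F, "p": p, "significant": p < ALPHA,
        })
    effects = pd.DataFrame(rows).set_index("effect")
    return AnovaTable(
        dependent=dependent,
        intercept=float(fit.params[0]),
        effects=effects,
        residual_var=resid_var,
        residual_dof=dof,
    )
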