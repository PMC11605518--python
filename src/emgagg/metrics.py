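"""Outcome measures for offline decoding and target-touching replay.

Accuracy is split into *intended* movement RMSE (error on the DOF(s) the
trial actively moves) and *unintended* movement RMSE (cross-talk: each
resting DOF's RMSE against its zero target, averaged over the resting
DOFs).  Target-touching trials additionally score the fraction of time all
DOFs sit within an absolute +/-0.15 window of their targets, the longest
continuous in-window hold, a windowed RMSE that forgives errors inside the
window, and the log mean absolute jerk as a smoothness measure.
Robustness over days is summarized by per-DOF least-squares slopes of RMSE
versus days since training.  Group contrasts use Kruskal-Wallis with
Nemenyi-style (studentized-range corrected) pairwise rank comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import N_DOF, DecodedTrace, KinematicTrace, TrialAnnotation


@dataclass
class TrialMetrics:
    """Per-trial outcome measures."""

    trial_id: int
    intended_rmse: float
    unintended_rmse: float
    pct_time_in_target: float | None = None
    max_hold_s: float | None = None
    log_mean_abs_jerk: float | None = None


@dataclass
class SlopeFit:
    """Least-squares RMSE-vs-days fit for one DOF."""

    dof_index: int
    slope: float
    intercept: float
    n_points: int


def _rmse(a: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(a))))


def intended_unintended_rmse(
    decoded: DecodedTrace,
    target: KinematicTrace,
    annotation: TrialAnnotation,
) -> tuple[float, float]:
    """Accuracy on the active DOF(s) and mean cross-talk on the resting DOFs.

    Intended: RMSE between decoded and target over the annotated span on
    the active DOF(s).  Unintended: each resting DOF's RMSE against its
    rest (zero) target, averaged across the resting DOFs.  Frames outside
    the annotated span never contribute.
    """
    if not annotation.active_dofs:
        raise ValueError("annotation has no active DOF")
    span = annotation.span()
    active = list(annotation.active_dofs)
    resting = [d for d in range(N_DOF) if d not in annotation.active_dofs]
    diff = decoded.values[:, span] - target.values[:, span]
    intended = _rmse(diff[active])
    per_dof = np.sqrt(np.mean(np.square(decoded.values[resting, span.start : span.stop]), axis=1))
    unintended = float(np.mean(per_dof))
    return intended, unintended


def windowed_rmse(
    decoded: DecodedTrace,
    target: KinematicTrace,
    window: float = 0.15,
    dof_indices: list[int] | None = None,
    span: slice | None = None,
) -> float:
    """RMSE that is zero anywhere inside the +/-``window`` error band.

    Per-frame error is ``max(0, |decoded - target| - window)`` before
    squaring, matching the visual feedback of the target-touching task.
    With ``window=0`` this is the plain RMSE.
    """
    if window < 0:
        raise ValueError("window must be nonnegative")
    dofs = list(range(N_DOF)) if dof_indices is None else list(dof_indices)
    span = span if span is not None else slice(None)
    err = np.abs(decoded.values[dofs, span] - target.values[dofs, span])
    return _rmse(np.maximum(err - window, 0.0))


def ttt_occupancy(
    decoded: DecodedTrace,
    target: KinematicTrace,
    window: float = 0.15,
    frame_rate: float = 30.0,
    span: slice | None = None,
) -> tuple[float, float]:
    """Percent time with every DOF in its target window, and longest hold.

    A frame counts only when all 12 DOFs are simultaneously within
    +/-``window`` of their targets (active DOFs near the target, resting
    DOFs near zero), mirroring the all-green condition of the online task.
    """
    span = span if span is not None else slice(None)
    err = np.abs(decoded.values[:, span] - target.values[:, span])
    if err.shape[1] == 0:
        raise ValueError("empty trial span")
    in_window = np.all(err <= window, axis=0)
    pct = 100.0 * float(np.mean(in_window))
    longest = run = 0
    for flag in in_window:
        run = run + 1 if flag else 0
        longest = max(longest, run)
    return pct, longest / frame_rate


def log_mean_abs_jerk(
    decoded: DecodedTrace,
    frame_rate: float = 30.0,
    dof_indices: list[int] | None = None,
    span: slice | None = None,
) -> float:
    """Natural log of the mean absolute third derivative (smoothness).

    The jerk is a third-order central finite difference scaled by
    ``frame_rate**3``, evaluated on the active DOFs only.  A constant
    trace has zero jerk; ``-inf`` is returned (with a warning) as the
    degenerate sentinel.
    """
    dofs = list(range(N_DOF)) if dof_indices is None else list(dof_indices)
    span = span if span is not None else slice(None)
    x = decoded.values[dofs, span]
    if x.shape[1] < 5:
        raise ValueError("need at least 5 frames to estimate jerk")
    # f'''(t) ~ (x[t+2] - 2 x[t+1] + 2 x[t-1] - x[t-2]) / 2 * fr^3
    jerk = (x[:, 4:] - 2.0 * x[:, 3:-1] + 2.0 * x[:, 1:-3] - x[:, :-4]) / 2.0 * frame_rate**3
    mean_abs = float(np.mean(np.abs(jerk)))
    if mean_abs < 1e-300:
        warnings.warn("constant trace: jerk is zero, returning -inf", stacklevel=2)
        return -np.inf
    return float(np.log(mean_abs))


def robustness_slopes(rmse_by_day: pd.DataFrame) -> list[SlopeFit]:
    """Per-DOF ordinary least-squares slope of RMSE versus days since training.

    ``rmse_by_day`` needs columns ``dof``, ``day_since_training``, ``rmse``.
    """
    required = {"dof", "day_since_training", "rmse"}
    if not required.issubset(rmse_by_day.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    fits: list[SlopeFit] = []
    for dof, group in rmse_by_day.groupby("dof"):
        days = group["day_since_training"].to_numpy(dtype=float)
        if np.unique(days).size < 2:
            raise ValueError(f"DOF {dof}: need at least two distinct days to fit a slope")
        slope, intercept = np.polyfit(days, group["rmse"].to_numpy(dtype=float), 1)
        fits.append(SlopeFit(dof_index=int(dof), slope=float(slope),
                             intercept=float(intercept), n_points=len(group)))
    return fits


def summarize_slopes(fits: list[SlopeFit]) -> dict:
    """Median and interquartile range of slopes across DOFs."""
    slopes = np.array([f.slope for f in fits])
    q1, med, q3 = np.percentile(slopes, [25, 50, 75])
    return {"median": float(med), "iqr": (float(q1), float(q3)), "n": len(fits)}


def compare_groups(
    samples_by_condition: dict[str, np.ndarray],
    alpha: float = 0.05,
) -> dict:
    """Kruskal-Wallis across conditions with corrected pairwise follow-ups.

    If the omnibus test is significant, all pairs are compared with
    Dunn/Nemenyi rank statistics whose p-values use the studentized-range
    distribution (the rank analogue of Tukey's HSD; approximate for ties).
    """
    names = list(samples_by_condition)
    if len(names) < 2:
        raise ValueError("need at least two conditions")
    groups = [np.asarray(samples_by_condition[n], dtype=float) for n in names]
    if any(g.size < 3 for g in groups):
        raise ValueError("need at least three samples per condition")
    pooled = np.concatenate(groups)
    if np.unique(pooled).size == 1:
        warnings.warn("all samples identical; omnibus p set to 1", stacklevel=2)
        return {"H": 0.0, "p": 1.0, "pairwise": []}
    H, p = stats.kruskal(*groups)

    pairwise = []
    if p < alpha:
        ranks = stats.rankdata(pooled)
        n_total = pooled.size
        k = len(groups)
        sizes = [g.size for g in groups]
        offsets = np.cumsum([0] + sizes)
        mean_ranks = [ranks[offsets[i] : offsets[i + 1]].mean() for i in range(k)]
        # Tie correction for the rank-variance term.
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = 1.0 - np.sum(counts**3 - counts) / (n_total**3 - n_total)
        for i in range(k):
            for j in range(i + 1, k):
                se = np.sqrt(
                    tie_term * n_total * (n_total + 1) / 12.0 * (1.0 / sizes[i] + 1.0 / sizes[j])
                )
                z = (mean_ranks[i] - mean_ranks[j]) / se
                p_adj = float(stats.studentized_range.sf(abs(z) * np.sqrt(2.0), k, np.inf))
                pairwise.append(
                    {
                        "conditions": (names[i], names[j]),
                        "z": float(z),
                        "p_adj": min(p_adj, 1.0),
                        "direction": names[i] if z < 0 else names[j],  # smaller mean rank
                    }
                )
    return {"H": float(H), "p": float(p), "pairwise": pairwise}
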