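"""Per-session task measures and data-quality exclusions.

Metacognitive bias is the mean confidence rating across a session's trials;
task difficulty is the mean dot difference (lower = harder); accuracy and
response time are simple per-session means.  Sessions are excluded when the
staircase failed to converge (mean accuracy strictly below 0.60 or strictly
above 0.85) or when one side was chosen on strictly more than 95% of trials.
The boundary values 0.60, 0.85 and 0.95 are retained; pass
``closed_bounds=True`` for the closed-interval variant.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .staircase import SessionData

__all__ = [
    "SessionMetrics",
    "compute_session_metrics",
    "apply_task_exclusions",
    "metrics_table",
    "split_half_reliability",
    "complete_case_filter",
]

ACCURACY_BOUNDS = (0.60, 0.85)
SIDE_BIAS_THRESHOLD = 0.95


@dataclass(frozen=True)
class SessionMetrics:
    participant_id: str
    timepoint: str
    n_trials: int
    mean_confidence: float
    mean_dot_difference: float
    mean_accuracy: float
    mean_rt: float
    side_proportion: float  # max over sides of the choice proportion
    excluded: bool = False
    reasons: tuple[str, ...] = ()


def compute_session_metrics(session: SessionData) -> SessionMetrics:
    """Simple per-session means; no exclusion flags are set here."""
    t = session.trials
    if len(t) == 0:
        raise ValueError(
            f"session {session.participant_id}/{session.timepoint} has no trials"
        )
    p_right = float((t["chosen_side"] == "right").mean())
    return SessionMetrics(
        participant_id=session.participant_id,
        timepoint=session.timepoint,
        n_trials=len(t),
        mean_confidence=float(t["confidence"].mean()),
        mean_dot_difference=float(t["dot_difference"].mean()),
        mean_accuracy=float(t["correct"].mean()),
        mean_rt=float(t["rt_s"].mean()),
        side_proportion=max(p_right, 1.0 - p_right),
    )


def apply_task_exclusions(
    metrics: SessionMetrics,
    accuracy_bounds: tuple[float, float] = ACCURACY_BOUNDS,
    side_bias_threshold: float = SIDE_BIAS_THRESHOLD,
    closed_bounds: bool = False,
) -> SessionMetrics:
    """Flag a session for exclusion; boundary values are retained by default."""
    lo, hi = accuracy_bounds
    reasons: list[str] = []
    if closed_bounds:
        bad_acc = metrics.mean_accuracy <= lo or metrics.mean_accuracy >= hi
        bad_side = metrics.side_proportion >= side_bias_threshold
    else:
        bad_acc = metrics.mean_accuracy < lo or metrics.mean_accuracy > hi
        bad_side = metrics.side_proportion > side_bias_threshold
    if bad_acc:
        reasons.append("accuracy")
    if bad_side:
        reasons.append("side-bias")
    return replace(metrics, excluded=bool(reasons), reasons=tuple(reasons))


def metrics_table(
    sessions: Sequence[SessionData],
    closed_bounds: bool = False,
) -> pd.DataFrame:
    """Metrics with exclusion flags for a collection of sessions."""
    rows = []
    for s in sessions:
        m = apply_task_exclusions(compute_session_metrics(s), closed_bounds=closed_bounds)
        rows.append(
            {
                "participant_id": m.participant_id,
                "timepoint": m.timepoint,
                "mean_confidence": m.mean_confidence,
                "mean_dot_difference": m.mean_dot_difference,
                "mean_accuracy": m.mean_accuracy,
                "mean_rt": m.mean_rt,
                "side_proportion": m.side_proportion,
                "excluded": m.excluded,
                "reasons": ";".join(m.reasons),
            }
        )
    return pd.DataFrame(rows)


def split_half_reliability(sessions: Sequence[SessionData]):
    """Odd/even split-half reliability of mean confidence: (r, df, p).

    For each session, mean confidence is computed separately over odd- and
    even-indexed trials (1-based, so trial 1 is odd); the Pearson
    correlation of the two halves across sessions is returned.
    """
    if len(sessions) < 3:
        raise ValueError("need at least three sessions")
    odd, even = [], []
    for s in sessions:
        t = s.trials
        if len(t) < 2:
            raise ValueError(
                f"session {s.participant_id}/{s.timepoint} has fewer than two trials"
            )
        is_odd = (t["trial"] % 2) == 1
        odd.append(float(t.loc[is_odd, "confidence"].mean()))
        even.append(float(t.loc[~is_odd, "confidence"].mean()))
    odd_a, even_a = np.asarray(odd), np.asarray(even)
    if odd_a.std() == 0 or even_a.std() == 0:
        raise ValueError("split-half correlation undefined: zero variance in a half")
    r, p = sps.pearsonr(odd_a, even_a)
    return float(r), len(sessions) - 2, float(p)


def complete_case_filter(
    metrics: pd.DataFrame,
    scores: pd.DataFrame | None = None,
    timepoints: tuple[str, str] = ("baseline", "followup"),
) -> list[str]:
    """Participant ids forming the completer analysis set.

    A completer has a non-excluded session and (when ``scores`` is given)
    complete dimension scores at both timepoints.
    """
    ok = metrics[~metrics["excluded"].astype(bool)]
    by_pid = ok.groupby("participant_id")["timepoint"].agg(set)
    keep = set(by_pid[by_pid.apply(lambda s: set(timepoints) <= s)].index)
    if scores is not None:
        complete = scores.dropna(subset=["AD", "CIT", "SW"])
        by_pid_s = complete.groupby("participant_id")["timepoint"].agg(set)
        keep &= set(by_pid_s[by_pid_s.apply(lambda s: set(timepoints) <= s)].index)
    order = {pid: i for i, pid in enumerate(pd.unique(metrics["participant_id"]))}
    return sorted(keep, key=lambda pid: order.get(pid, len(order)))
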