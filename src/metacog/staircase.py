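"""Adaptive two-down one-up dot-difference staircase.

The perceptual task pairs two dot patches ("sunflowers") and asks which
contains more dots, followed by a confidence rating on a 1-6 scale.  Task
difficulty is the *dot difference* between the two patches, manipulated in
log space by a two-down one-up (2D1U) staircase: difficulty increases
(dot difference shrinks) after two consecutive correct responses and
decreases (dot difference grows) after every error.  The 2D1U rule
asymptotically tracks the difficulty at which the probability of a correct
response is sqrt(0.5) ~ 0.707, so observed accuracy is pinned near 70%
regardless of perceptual ability — the property that makes mean confidence
interpretable as metacognitive bias rather than a performance readout.

The staircase starts at a log difference of 4.2, steps by 0.4 in log units
for the first five trials, 0.2 for the next five, and 0.1 thereafter, and is
clamped so the integer dot difference stays within [6, 81]
(ln 6 ~ 1.79, ln 81 ~ 4.39).  A session is 210 trials in five equal blocks;
the staircase runs continuously across blocks.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StaircaseConfig",
    "StaircaseState",
    "TrialRecord",
    "SessionData",
    "Observer",
    "step_size_for_trial",
    "update_staircase",
    "dots_from_logdiff",
    "run_session",
    "write_sessions",
    "read_sessions",
]

#: Columns of the trial-level delimited output, in order.
TRIAL_COLUMNS = [
    "participant_id",
    "timepoint",
    "trial",
    "dot_difference",
    "target_side",
    "chosen_side",
    "correct",
    "confidence",
    "rt_s",
]


@dataclass(frozen=True)
class StaircaseConfig:
    """Parameters of the adaptive dot-difference task.

    ``step_schedule`` is a sequence of ``(first_trial, last_trial, step)``
    entries over 1-based session trial indices; ``last_trial=None`` means
    "to the end of the session".  Steps are log-space magnitudes.
    """

    n_trials: int = 210
    n_blocks: int = 5
    start_log_diff: float = 4.2
    step_schedule: tuple[tuple[int, int | None, float], ...] = (
        (1, 5, 0.4),
        (6, 10, 0.2),
        (11, None, 0.1),
    )
    min_dots: int = 6
    max_dots: int = 81
    fixation_ms: int = 1000
    stimulus_ms: int = 300
    feedback_ms: int = 500
    confidence_levels: int = 6

    def __post_init__(self) -> None:
        if self.n_trials <= 0 or self.n_blocks <= 0:
            raise ValueError("n_trials and n_blocks must be positive")
        if self.n_trials % self.n_blocks != 0:
            raise ValueError(
                f"n_trials={self.n_trials} is not divisible into "
                f"{self.n_blocks} equal blocks"
            )
        if not (0 < self.min_dots < self.max_dots):
            raise ValueError("require 0 < min_dots < max_dots")
        start_dots = math.floor(math.exp(self.start_log_diff) + 0.5)
        if not (self.min_dots < start_dots <= self.max_dots):
            raise ValueError(
                f"start_log_diff={self.start_log_diff} maps to {start_dots} "
                f"dots, outside ({self.min_dots}, {self.max_dots}]"
            )
        steps = [s for _, _, s in self.step_schedule]
        if any(s <= 0 for s in steps):
            raise ValueError("step sizes must be strictly positive")
        if any(a < b for a, b in zip(steps, steps[1:])):
            raise ValueError("step sizes must be non-increasing over the schedule")
        # schedule must tile 1..n_trials contiguously
        expected_start = 1
        for first, last, _ in self.step_schedule:
            if first != expected_start:
                raise ValueError("step_schedule ranges must be contiguous from trial 1")
            expected_start = (self.n_trials if last is None else last) + 1
        if expected_start != self.n_trials + 1:
            raise ValueError("step_schedule does not cover every trial")

    @property
    def log_min(self) -> float:
        return math.log(self.min_dots)

    @property
    def log_max(self) -> float:
        return math.log(self.max_dots)


@dataclass(frozen=True)
class StaircaseState:
    """Mutable-by-replacement staircase position.

    ``trial_index`` is the 1-based index of the *next* trial to be run;
    ``consecutive_correct`` is the 2D1U counter and is always 0 or 1.
    """

    trial_index: int
    log_diff: float
    consecutive_correct: int = 0

    def __post_init__(self) -> None:
        if self.trial_index < 1:
            raise ValueError("trial_index is 1-based")
        if self.consecutive_correct not in (0, 1):
            raise ValueError("consecutive_correct must be 0 or 1")


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int
    dot_difference: int
    target_side: str
    chosen_side: str
    correct: bool
    confidence: int
    rt: float


@dataclass
class SessionData:
    """One participant x timepoint run of the task.

    ``trials`` is a DataFrame with columns ``trial, dot_difference,
    target_side, chosen_side, correct, confidence, rt_s``.
    """

    participant_id: str
    timepoint: str
    trials: pd.DataFrame

    @property
    def n_trials(self) -> int:
        return len(self.trials)


class Observer(Protocol):
    """Anything that can respond to a single staircase trial.

    Observers receive the trial's log dot difference and the target side but
    no accuracy feedback (the task shows only the chosen side), so they must
    not adapt on correctness.
    """

    def respond(
        self, log_diff: float, target_side: str, rng: np.random.Generator
    ) -> tuple[str, int, float]:
        """Return ``(chosen_side, confidence, rt_seconds)``."""
        ...


def step_size_for_trial(trial_index: int, config: StaircaseConfig | None = None) -> float:
    """Scheduled log-space step magnitude for a 1-based session trial index."""
    config = config or StaircaseConfig()
    if not 1 <= trial_index <= config.n_trials:
        raise ValueError(
            f"trial_index={trial_index} outside 1..{config.n_trials}"
        )
    for first, last, step in config.step_schedule:
        last_eff = config.n_trials if last is None else last
        if first <= trial_index <= last_eff:
            return step
    raise AssertionError("unreachable: schedule validated to cover all trials")


def update_staircase(
    state: StaircaseState, correct: bool, config: StaircaseConfig | None = None
) -> StaircaseState:
    """Apply the 2D1U rule to the trial just completed at ``state.trial_index``.

    Incorrect: step up (easier), counter reset.  Correct with counter 0:
    hold, counter 1.  Correct with counter 1: step down (harder), counter
    reset.  The counter resets after every step in either direction.  The
    result is clamped in log space to [ln min_dots, ln max_dots].
    """
    config = config or StaircaseConfig()
    step = step_size_for_trial(state.trial_index, config)
    if not correct:
        log_diff = state.log_diff + step
        counter = 0
    elif state.consecutive_correct == 0:
        log_diff = state.log_diff
        counter = 1
    else:
        log_diff = state.log_diff - step
        counter = 0
    log_diff = min(max(log_diff, config.log_min), config.log_max)
    return StaircaseState(
        trial_index=state.trial_index + 1,
        log_diff=log_diff,
        consecutive_correct=counter,
    )


def dots_from_logdiff(log_diff: float, config: StaircaseConfig | None = None) -> int:
    """Integer dot difference shown for a log-space difficulty (round half-up)."""
    config = config or StaircaseConfig()
    if not math.isfinite(log_diff):
        raise ValueError(f"log_diff must be finite, got {log_diff}")
    dots = math.floor(math.exp(log_diff) + 0.5)
    return min(max(dots, config.min_dots), config.max_dots)


def run_session(
    observer: Observer,
    config: StaircaseConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
    participant_id: str = "obs",
    timepoint: str = "baseline",
) -> SessionData:
    """Run one full staircase session against an observer.

    The target side is drawn uniformly each trial.  Runs are bit-reproducible
    given the seed.  An observer returning a confidence outside
    ``1..confidence_levels`` or a non-positive RT violates its contract.
    """
    config = config or StaircaseConfig()
    rng = np.random.default_rng(seed)
    state = StaircaseState(trial_index=1, log_diff=config.start_log_diff)
    n = config.n_trials
    dots = np.empty(n, dtype=np.int64)
    target = np.empty(n, dtype=object)
    chosen = np.empty(n, dtype=object)
    correct = np.empty(n, dtype=bool)
    confidence = np.empty(n, dtype=np.int64)
    rt = np.empty(n, dtype=float)

    for i in range(n):
        t_side = "right" if rng.random() < 0.5 else "left"
        c_side, conf, rt_i = observer.respond(state.log_diff, t_side, rng)
        if c_side not in ("left", "right"):
            raise ValueError(f"observer returned invalid side {c_side!r}")
        if not (isinstance(conf, (int, np.integer)) and 1 <= conf <= config.confidence_levels):
            raise ValueError(
                f"observer returned confidence {conf!r} outside "
                f"1..{config.confidence_levels}"
            )
        if not rt_i > 0:
            raise ValueError(f"observer returned non-positive RT {rt_i!r}")
        dots[i] = dots_from_logdiff(state.log_diff, config)
        target[i] = t_side
        chosen[i] = c_side
        correct[i] = c_side == t_side
        confidence[i] = int(conf)
        rt[i] = float(rt_i)
        state = update_staircase(state, bool(correct[i]), config)

    trials = pd.DataFrame(
        {
            "trial": np.arange(1, n + 1),
            "dot_difference": dots,
            "target_side": target,
            "chosen_side": chosen,
            "correct": correct,
            "confidence": confidence,
            "rt_s": rt,
        }
    )
    return SessionData(participant_id=participant_id, timepoint=timepoint, trials=trials)


def sessions_to_frame(sessions: Sequence[SessionData]) -> pd.DataFrame:
    """Stack sessions into the long trial-level table (one row per trial)."""
    frames = []
    for s in sessions:
        f = s.trials.copy()
        f.insert(0, "timepoint", s.timepoint)
        f.insert(0, "participant_id", s.participant_id)
        frames.append(f)
    if not frames:
        return pd.DataFrame(columns=TRIAL_COLUMNS)
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]


def frame_to_sessions(frame: pd.DataFrame) -> list[SessionData]:
    """Inverse of :func:`sessions_to_frame`; preserves first-seen order."""
    sessions = []
    for (pid, tp), grp in frame.groupby(["participant_id", "timepoint"], sort=False):
        trials = grp.drop(columns=["participant_id", "timepoint"]).reset_index(drop=True)
        sessions.append(SessionData(str(pid), str(tp), trials))
    return sessions


def write_sessions(sessions: Sequence[SessionData], path) -> None:
    """Write sessions as headered CSV, one row per trial."""
    sessions_to_frame(sessions).to_csv(path, index=False)


def read_sessions(path) -> list[SessionData]:
    frame = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"trial file {path} is missing columns {sorted(missing)}")
    frame["correct"] = frame["correct"].astype(bool)
    return frame_to_sessions(frame)
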