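"""Synthetic volatile two-armed bandit task with an advice cue.

The task couples two independent probabilistic schedules:

* a *reward* schedule giving the per-trial probability that the blue
  option is rewarded, with p(green) = 1 - p(blue);
* an *advice* schedule giving the per-trial probability that a frame
  ("advice") highlights the option that will turn out to be correct.

Each schedule alternates one *stable* phase (constant probability for
50-60 trials) with a *volatile* phase in which the probability reverses
(p -> 1 - p) every 10-30 trials.  Sessions are 120 trials by default.

Coding conventions used throughout the package:

* ``outcome``: 1 = blue rewarded, 0 = green rewarded.
* ``advice``:  0 = frame on blue, 1 = frame on green.
* ``choice``:  1 = blue chosen,  0 = green chosen.
* ``advice_correct``: 1 iff the advised option equals the outcome option,
  i.e. ``advice == 1 - outcome``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import cached_property
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

STABLE = "stable"
VOLATILE = "volatile"

DEFAULT_LEVELS = (0.2, 0.25, 0.75, 0.8)

#: The four counterbalanced schedule layouts: the 2x2 crossing of whether
#: the reward and advice schedules start with their stable phase.  Seeds
#: are fixed per layout so every cohort shares the same four schedules,
#: mirroring random allocation of participants to pre-programmed schedules.
CANONICAL_LAYOUTS: dict[int, tuple[bool, bool]] = {
    1: (True, True),
    2: (True, False),
    3: (False, True),
    4: (False, False),
}
_LAYOUT_SEED_BASE = 7200


class ScheduleConstructionError(ValueError):
    """Raised when no phase layout satisfies the length constraints."""


@dataclass(frozen=True)
class PhaseSegment:
    """A maximal run of trials with constant probability.

    ``start_trial`` is 0-based inclusive; the segment covers
    ``[start_trial, start_trial + length)``.
    """

    start_trial: int
    length: int
    p: float
    volatility_label: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"segment p={self.p} outside [0, 1]")
        if self.volatility_label not in (STABLE, VOLATILE):
            raise ValueError(f"unknown volatility label {self.volatility_label!r}")
        if self.length < 1:
            raise ValueError("segment length must be >= 1")


@dataclass(frozen=True)
class TaskSchedule:
    """Per-trial probability and stable/volatile label for one schedule."""

    n_trials: int
    segments: tuple[PhaseSegment, ...]
    kind: str  # "reward" or "advice"

    def __post_init__(self) -> None:
        if self.kind not in ("reward", "advice"):
            raise ValueError(f"kind must be 'reward' or 'advice', got {self.kind!r}")
        pos = 0
        for seg in self.segments:
            if seg.start_trial != pos:
                raise ValueError("segments must tile trials without gap or overlap")
            pos += seg.length
        if pos != self.n_trials:
            raise ValueError("segments do not cover n_trials exactly")

    @cached_property
    def per_trial_p(self) -> np.ndarray:
        out = np.empty(self.n_trials)
        for seg in self.segments:
            out[seg.start_trial : seg.start_trial + seg.length] = seg.p
        return out

    @cached_property
    def per_trial_volatility(self) -> np.ndarray:
        out = np.empty(self.n_trials, dtype=object)
        for seg in self.segments:
            out[seg.start_trial : seg.start_trial + seg.length] = seg.volatility_label
        return np.asarray(out, dtype="U8")

    @cached_property
    def per_trial_volatile(self) -> np.ndarray:
        """Boolean mask, True where the phase is volatile."""
        return self.per_trial_volatility == VOLATILE


@dataclass
class TrialSequence:
    """One session's trial-level data."""

    outcome: np.ndarray
    advice: np.ndarray
    advice_correct: np.ndarray
    choice: np.ndarray | None = None
    followed_advice: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.outcome = np.asarray(self.outcome, dtype=int)
        self.advice = np.asarray(self.advice, dtype=int)
        self.advice_correct = np.asarray(self.advice_correct, dtype=int)
        n = len(self.outcome)
        if len(self.advice) != n or len(self.advice_correct) != n:
            raise ValueError("outcome/advice/advice_correct lengths differ")
        if not np.array_equal(self.advice_correct, (self.advice == 1 - self.outcome).astype(int)):
            raise ValueError("advice_correct inconsistent with advice/outcome coding")
        if self.choice is not None:
            self.choice = np.asarray(self.choice, dtype=int)
            if len(self.choice) != n:
                raise ValueError("choice length differs")
            followed = (self.choice == 1 - self.advice).astype(int)
            if self.followed_advice is None:
                self.followed_advice = followed
            elif not np.array_equal(np.asarray(self.followed_advice, dtype=int), followed):
                raise ValueError("followed_advice inconsistent with choice/advice")

    @property
    def n_trials(self) -> int:
        return len(self.outcome)


def _draw_stable_length(n_trials: int, rng: np.random.Generator) -> int:
    # Valid stable lengths: 50-60, leaving either nothing or >= 10 volatile
    # trials (a volatile phase shorter than one change interval cannot exist).
    candidates = [
        L for L in range(50, 61)
        if L <= n_trials and (n_trials - L == 0 or n_trials - L >= 10)
    ]
    if not candidates:
        raise ScheduleConstructionError(
            f"n_trials={n_trials} cannot host a 50-60 trial stable phase "
            "plus a valid volatile phase"
        )
    return int(rng.choice(candidates))


def _partition_volatile(total: int, rng: np.random.Generator) -> list[int]:
    """Partition ``total`` volatile trials into change intervals of 10-30."""
    intervals: list[int] = []
    remaining = total
    while remaining > 30:
        hi = min(30, remaining - 10)
        draw = int(rng.integers(10, hi + 1))
        intervals.append(draw)
        remaining -= draw
    if remaining:
        intervals.append(remaining)
    return intervals


def generate_schedule(
    n_trials: int = 120,
    kind: str = "reward",
    stable_first: bool = True,
    seed: int | None = None,
    levels: Sequence[float] = DEFAULT_LEVELS,
) -> TaskSchedule:
    """Generate a schedule with one stable phase and a volatile remainder.

    The stable phase length is drawn uniformly from the valid subset of
    50-60 trials; the volatile remainder is split into change intervals
    drawn uniformly from 10-30 trials.  The probability flips to ``1 - p``
    at every segment boundary (including the stable/volatile boundary),
    so with the default level set the probability always stays in
    ``[0.2, 0.8]``.
    """
    if n_trials < 50:
        raise ScheduleConstructionError("n_trials must be >= 50")
    levels = tuple(float(p) for p in levels)
    if any(not 0.2 <= p <= 0.8 for p in levels):
        raise ValueError("probability levels must lie in [0.2, 0.8]")
    rng = np.random.default_rng(seed)
    stable_len = _draw_stable_length(n_trials, rng)
    volatile_lengths = _partition_volatile(n_trials - stable_len, rng)

    if stable_first:
        lengths = [stable_len] + volatile_lengths
        labels = [STABLE] + [VOLATILE] * len(volatile_lengths)
    else:
        lengths = volatile_lengths + [stable_len]
        labels = [VOLATILE] * len(volatile_lengths) + [STABLE]

    p = float(rng.choice(levels))
    segments = []
    pos = 0
    for i, (L, lab) in enumerate(zip(lengths, labels)):
        seg_p = p if i % 2 == 0 else round(1.0 - p, 12)
        segments.append(PhaseSegment(pos, int(L), seg_p, lab))
        pos += int(L)
    return TaskSchedule(n_trials=n_trials, segments=tuple(segments), kind=kind)


def canonical_schedules(
    layout_id: int,
    n_trials: int = 120,
    levels: Sequence[float] = DEFAULT_LEVELS,
) -> tuple[TaskSchedule, TaskSchedule]:
    """Return the fixed (reward, advice) schedule pair for a layout id (1-4)."""
    if layout_id not in CANONICAL_LAYOUTS:
        raise ValueError(f"layout_id must be in {sorted(CANONICAL_LAYOUTS)}")
    reward_first, advice_first = CANONICAL_LAYOUTS[layout_id]
    reward = generate_schedule(
        n_trials, "reward", reward_first, seed=_LAYOUT_SEED_BASE + 2 * layout_id, levels=levels
    )
    advice = generate_schedule(
        n_trials, "advice", advice_first, seed=_LAYOUT_SEED_BASE + 2 * layout_id + 1, levels=levels
    )
    return reward, advice


def _draw_binary(p: np.ndarray, segments: Sequence[PhaseSegment], mode: str,
                 rng: np.random.Generator) -> np.ndarray:
    if mode == "bernoulli":
        return (rng.random(len(p)) < p).astype(int)
    if mode == "exact_proportion":
        out = np.empty(len(p), dtype=int)
        for seg in segments:
            n_hit = int(round(seg.length * seg.p))
            block = np.zeros(seg.length, dtype=int)
            block[:n_hit] = 1
            rng.shuffle(block)
            out[seg.start_trial : seg.start_trial + seg.length] = block
        return out
    raise ValueError(f"mode must be 'bernoulli' or 'exact_proportion', got {mode!r}")


def generate_outcomes(
    schedule: TaskSchedule,
    mode: str = "bernoulli",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw per-trial outcomes (1 = blue rewarded) from a reward schedule."""
    if schedule.kind != "reward":
        raise ValueError("generate_outcomes requires a reward schedule")
    if rng is None:
        rng = np.random.default_rng(seed)
    return _draw_binary(schedule.per_trial_p, schedule.segments, mode, rng)


def generate_advice(
    advice_schedule: TaskSchedule,
    outcomes: np.ndarray,
    mode: str = "bernoulli",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw advice-correctness per the advice schedule, then place the frame.

    When the advice is correct the frame highlights the outcome option;
    otherwise the other option.  Returns ``(advice, advice_correct)`` with
    advice coded 0 = blue, 1 = green.
    """
    outcomes = np.asarray(outcomes, dtype=int)
    if len(outcomes) != advice_schedule.n_trials:
        raise ValueError("outcomes length does not match the advice schedule")
    if rng is None:
        rng = np.random.default_rng(seed)
    correct = _draw_binary(advice_schedule.per_trial_p, advice_schedule.segments, mode, rng)
    # correct advice points at the outcome option: advice == 1 - outcome
    advice = np.where(correct == 1, 1 - outcomes, outcomes)
    return advice.astype(int), correct.astype(int)


def simulate_agent(
    params,
    reward_schedule: TaskSchedule,
    advice_schedule: TaskSchedule,
    outcomes: np.ndarray,
    advice: np.ndarray,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> TrialSequence:
    """Simulate choices from the dual Rescorla-Wagner agent.

    Value updates are driven by the outcome and advice sequences alone
    (full feedback: the outcome indicator is always shown), so the trace
    is computed once and choices are sampled from the per-trial blue-choice
    probabilities.
    """
    from .model import run_model  # local import to avoid a cycle

    outcomes = np.asarray(outcomes, dtype=int)
    advice = np.asarray(advice, dtype=int)
    advice_correct = (advice == 1 - outcomes).astype(int)
    trials = TrialSequence(outcome=outcomes, advice=advice, advice_correct=advice_correct)
    trace = run_model(params, trials, reward_schedule, advice_schedule)
    if rng is None:
        rng = np.random.default_rng(seed)
    choice = (rng.random(len(outcomes)) < trace.p_blue).astype(int)
    return TrialSequence(
        outcome=outcomes, advice=advice, advice_correct=advice_correct, choice=choice
    )


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class CohortSpec:
    """Specification for a simulated cohort (two sessions per subject)."""

    n_subjects: int
    params_distribution: Mapping[str, object] = field(default_factory=dict)
    schedule_ids: Sequence[int] | None = None
    seed: int = 0
    n_trials: int = 120
    outcome_mode: str = "bernoulli"

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")


#: Default generating ranges for cohort parameters.  Stable-phase learning
#: rates are drawn lower than volatile-phase ones on average, reflecting
#: the adaptive pattern the model family is designed to detect.
DEFAULT_PARAM_RANGES: dict[str, tuple[float, float]] = {
    "alpha_stable_experienced": (0.10, 0.40),
    "alpha_volatile_experienced": (0.20, 0.60),
    "alpha_stable_inferred": (0.10, 0.40),
    "alpha_volatile_inferred": (0.20, 0.60),
    "beta": (1.0, 6.0),
    "zeta": (0.2, 0.8),
}


def _sample_params(dist: Mapping[str, object], rng: np.random.Generator):
    from .model import ModelParams

    values = {}
    for name, default_range in DEFAULT_PARAM_RANGES.items():
        spec = dist.get(name, default_range)
        if isinstance(spec, (int, float)):
            values[name] = float(spec)
        else:
            lo, hi = spec  # type: ignore[misc]
            values[name] = float(rng.uniform(lo, hi))
    return ModelParams(**values)


@dataclass
class SessionRecord:
    subject_id: int
    session_id: str  # "A" or "B"
    schedule_id: int
    trials: TrialSequence
    reward_schedule: TaskSchedule
    advice_schedule: TaskSchedule
    true_params: object | None = None


def make_cohort(spec: CohortSpec) -> list[SessionRecord]:
    """Simulate a cohort: two sessions per subject, identical schedules,
    independently drawn outcomes, advice, and choices per session."""
    rng = np.random.default_rng(spec.seed)
    schedule_ids = list(spec.schedule_ids) if spec.schedule_ids else sorted(CANONICAL_LAYOUTS)
    records: list[SessionRecord] = []
    for subj in range(spec.n_subjects):
        sched_id = schedule_ids[subj % len(schedule_ids)]
        reward, advice_sched = canonical_schedules(sched_id, n_trials=spec.n_trials)
        params = _sample_params(spec.params_distribution, rng)
        for session_id in ("A", "B"):
            outcomes = generate_outcomes(reward, mode=spec.outcome_mode, rng=rng)
            advice, _ = generate_advice(advice_sched, outcomes, mode=spec.outcome_mode, rng=rng)
            trials = simulate_agent(params, reward, advice_sched, outcomes, advice, rng=rng)
            records.append(
                SessionRecord(subj, session_id, sched_id, trials, reward, advice_sched, params)
            )
    return records


# ---------------------------------------------------------------------------
# Serialisation

SESSION_COLUMNS = [
    "trial", "p_blue", "reward_phase", "p_advice_correct", "advice_phase",
    "outcome", "advice", "advice_correct", "choice", "followed_advice",
]


def session_to_frame(
    trials: TrialSequence,
    reward_schedule: TaskSchedule,
    advice_schedule: TaskSchedule,
) -> pd.DataFrame:
    """Tabulate one session, trial numbers 1-based for human consumption."""
    n = trials.n_trials
    frame = pd.DataFrame(
        {
            "trial": np.arange(1, n + 1),
            "p_blue": reward_schedule.per_trial_p,
            "reward_phase": reward_schedule.per_trial_volatility,
            "p_advice_correct": advice_schedule.per_trial_p,
            "advice_phase": advice_schedule.per_trial_volatility,
            "outcome": trials.outcome,
            "advice": trials.advice,
            "advice_correct": trials.advice_correct,
            "choice": trials.choice if trials.choice is not None else np.full(n, -1),
            "followed_advice": (
                trials.followed_advice if trials.followed_advice is not None else np.full(n, -1)
            ),
        }
    )
    return frame[SESSION_COLUMNS]


def _segments_from_per_trial(p: np.ndarray, labels: np.ndarray) -> tuple[PhaseSegment, ...]:
    segments = []
    start = 0
    for i in range(1, len(p) + 1):
        if i == len(p) or p[i] != p[start] or labels[i] != labels[start]:
            segments.append(PhaseSegment(start, i - start, float(p[start]), str(labels[start])))
            start = i
    return tuple(segments)


def frame_to_session(
    frame: pd.DataFrame,
) -> tuple[TrialSequence, TaskSchedule, TaskSchedule]:
    """Inverse of :func:`session_to_frame`."""
    missing = [c for c in SESSION_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"session table missing columns: {missing}")
    frame = frame.sort_values("trial").reset_index(drop=True)
    n = len(frame)
    reward = TaskSchedule(
        n, _segments_from_per_trial(frame["p_blue"].to_numpy(),
                                    frame["reward_phase"].to_numpy()), "reward"
    )
    advice_sched = TaskSchedule(
        n, _segments_from_per_trial(frame["p_advice_correct"].to_numpy(),
                                    frame["advice_phase"].to_numpy()), "advice"
    )
    choice = frame["choice"].to_numpy()
    trials = TrialSequence(
        outcome=frame["outcome"].to_numpy(),
        advice=frame["advice"].to_numpy(),
        advice_correct=frame["advice_correct"].to_numpy(),
        choice=None if (choice < 0).any() else choice,
    )
    return trials, reward, advice_sched


def cohort_metadata(records: Sequence[SessionRecord]) -> dict:
    """JSON-serialisable truth metadata for a simulated cohort."""
    from dataclasses import asdict

    subjects: dict[str, dict] = {}
    for rec in records:
        entry = subjects.setdefault(
            str(rec.subject_id), {"schedule_id": rec.schedule_id, "sessions": []}
        )
        if rec.session_id not in entry["sessions"]:
            entry["sessions"].append(rec.session_id)
        if rec.true_params is not None and "true_params" not in entry:
            entry["true_params"] = asdict(rec.true_params)
    return {"n_subjects": len(subjects), "subjects": subjects}


def write_cohort(records: Sequence[SessionRecord], out_dir) -> list[str]:
    """Write per-session CSVs and a truth JSON; returns written file names."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for rec in records:
        name = f"sub{rec.subject_id:03d}_ses{rec.session_id}.csv"
        session_to_frame(rec.trials, rec.reward_schedule, rec.advice_schedule).to_csv(
            out / name, index=False
        )
        written.append(name)
    meta = cohort_metadata(records)
    (out / "cohort.json").write_text(json.dumps(meta, indent=2))
    written.append("cohort.json")
    return written


def read_cohort(data_dir) -> list[SessionRecord]:
    """Read a cohort directory written by :func:`write_cohort`."""
    from pathlib import Path

    data = Path(data_dir)
    meta = json.loads((data / "cohort.json").read_text()) if (data / "cohort.json").exists() else None
    records = []
    for path in sorted(data.glob("sub*_ses*.csv")):
        stem = path.stem  # subNNN_sesX
        subj = int(stem[3:6])
        session_id = stem.split("_ses")[1]
        trials, reward, advice_sched = frame_to_session(pd.read_csv(path))
        sched_id = -1
        true_params = None
        if meta is not None and str(subj) in meta["subjects"]:
            entry = meta["subjects"][str(subj)]
            sched_id = entry.get("schedule_id", -1)
            if "true_params" in entry:
                from .model import ModelParams

                true_params = ModelParams(**entry["true_params"])
        records.append(
            SessionRecord(subj, session_id, sched_id, trials, reward, advice_sched, true_params)
        )
    return records
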