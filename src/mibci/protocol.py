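"""The neurofeedback training-protocol layer.

Covers the competence-test cue schedule (9 series x 6 trials per task x 3
tasks = 162 cues, preceded by two 1-minute rest baselines), evaluation of
closed-loop exercises against a decoded label stream, the per-session
success rate, and a composite difficulty score.

Exercise validation is dwell-based by default: a segment completes once the
cumulative time the decoder has emitted the segment's state reaches the
required hold (each decision contributes one step of dwell); segments must
complete in order, and the exercise succeeds iff the final segment
completes within the allotted time.  Cumulative dwell is robust to the
label flicker inherent to a 16 Hz decision stream; a stricter
consecutive-hold mode (dwell resets on any wrong label) is available.

The difficulty score is a declared stand-in combining the two published
ingredients — number of mental states and temporal tightness:
``score = n_states * (sum of required holds / allotted time)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recording import TASKS
from .streaming import DecisionStream


@dataclass(frozen=True)
class CueSchedule:
    """Cue sequence for a competence test / open-loop calibration run."""

    cues: tuple              # of (series_index, task)
    baselines: tuple = (("rest_eyes_open", 60.0), ("rest_eyes_closed", 60.0))

    def __len__(self) -> int:
        return len(self.cues)

    def count(self, task: str) -> int:
        return sum(1 for _, t in self.cues if t == task)


def schedule_competence_test(n_series: int = 9, trials_per_task: int = 6,
                             tasks=TASKS, seed: int | None = None) -> CueSchedule:
    """Seeded-random balanced cue schedule.

    Each series contains exactly ``trials_per_task`` cues of every task in
    random order (162 cues, 54 per task at defaults).  The two 1-minute rest
    baselines are carried as metadata.
    """
    if n_series < 1 or trials_per_task < 1 or len(tasks) < 1:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)
    cues = []
    for s in range(n_series):
        block = [task for task in tasks for _ in range(trials_per_task)]
        rng.shuffle(block)
        cues += [(s, task) for task in block]
    return CueSchedule(cues=tuple(cues))


@dataclass(frozen=True)
class Exercise:
    """An ordered sequence of (state, required hold s) under a time budget."""

    sequence: tuple          # of (state label, hold s)
    allotted_time: float

    def __post_init__(self):
        object.__setattr__(self, "sequence", tuple(
            (str(s), float(h)) for s, h in self.sequence))
        if any(h <= 0 for _, h in self.sequence):
            raise ValueError("required holds must be positive")
        unknown = {s for s, _ in self.sequence} - set(TASKS)
        if unknown:
            raise ValueError(f"states {sorted(unknown)} are not in the task set")
        if self.allotted_time < self.total_hold:
            raise ValueError("allotted_time must cover the summed holds")

    @property
    def n_states(self) -> int:
        return len(self.sequence)

    @property
    def total_hold(self) -> float:
        return sum(h for _, h in self.sequence)


@dataclass(frozen=True)
class ExerciseResult:
    success: bool
    attempts: int = 1
    completion_time: float | None = None
    achieved_holds: tuple = ()

    def __post_init__(self):
        if self.success != (self.completion_time is not None):
            raise ValueError("completion_time must be present iff success")


def evaluate_exercise(stream: DecisionStream, ex: Exercise,
                      start_time: float | None = None,
                      mode: str = "dwell") -> ExerciseResult:
    """Score one exercise attempt against a decoded label stream.

    Decisions from ``start_time`` (default: the first decision) onwards each
    contribute one ``stream.step`` of dwell toward the current segment when
    their label matches its state.  In ``consecutive`` mode a wrong label
    resets the current segment's dwell.  Failure when the allotted time
    elapses before the final segment completes (or the stream ends).
    """
    if mode not in ("dwell", "consecutive"):
        raise ValueError("mode must be 'dwell' or 'consecutive'")
    if len(stream) == 0:
        return ExerciseResult(success=False, attempts=1)
    t0 = stream.times[0] if start_time is None else start_time
    sel = stream.times >= t0 - 1e-9
    labels = stream.labels[sel]
    dt = stream.step
    seg = 0
    dwell = [0.0] * ex.n_states
    for i, lab in enumerate(labels):
        elapsed = (i + 1) * dt
        if elapsed > ex.allotted_time + 1e-9:
            break
        state, hold = ex.sequence[seg]
        if lab == state:
            dwell[seg] += dt
        elif mode == "consecutive":
            dwell[seg] = 0.0
        if dwell[seg] >= hold - 1e-9:
            seg += 1
            if seg == ex.n_states:
                return ExerciseResult(success=True, attempts=1,
                                      completion_time=elapsed,
                                      achieved_holds=tuple(dwell))
    return ExerciseResult(success=False, attempts=1,
                          achieved_holds=tuple(dwell))


def difficulty_score(ex: Exercise) -> float:
    """Composite difficulty: ``n_states * (total hold / allotted time)``.

    Dimensionless and positive; grows with the number of states and with
    temporal tightness; invariant to state relabeling and to permuting
    equal-hold segments.
    """
    if ex.allotted_time <= 0:
        raise ValueError("allotted_time must be positive")
    return ex.n_states * (ex.total_hold / ex.allotted_time)


@dataclass
class SessionRecord:
    """One training session: evaluated exercises plus derived metrics."""

    session_index: int       # t1..t10
    exercises: list = field(default_factory=list)  # (Exercise, ExerciseResult)

    @property
    def difficulties(self) -> list[float]:
        return [difficulty_score(ex) for ex, _ in self.exercises]

    @property
    def success_rate(self) -> float:
        return session_success_rate(self)


def session_success_rate(rec: SessionRecord) -> float:
    """Successfully completed exercises divided by attempts in the session."""
    attempts = sum(r.attempts for _, r in rec.exercises)
    if attempts == 0:
        raise ValueError("success rate undefined for zero attempts")
    return sum(1 for _, r in rec.exercises if r.success) / attempts


# ---------------------------------------------------------------------------
# Demo course simulation
# ---------------------------------------------------------------------------

def ramped_exercise(session_index: int, hold_s: float = 3.0,
                    base_slack: float = 3.0) -> Exercise:
    """Default difficulty ramp for simulated courses: one more state every 3
    sessions, 25% more temporal tightness every 2 sessions."""
    if session_index < 1:
        raise ValueError("session_index starts at 1")
    n_states = 1 + (session_index - 1) // 3
    cycle = ("right_hand", "relax", "left_hand")
    states = [cycle[i % 3] for i in range(n_states)]
    slack = base_slack / 1.25 ** ((session_index - 1) // 2)
    seq = tuple((s, hold_s) for s in states)
    return Exercise(sequence=seq, allotted_time=n_states * hold_s * max(slack, 1.1))


def simulate_training_course(n_sessions: int = 10, erd_depth: float = 0.5,
                             snr: float = 4.0, seed: int = 0,
                             exercises_per_session: int = 6,
                             calibration_series: int = 3,
                             trials_per_task: int = 3) -> list[SessionRecord]:
    """End-to-end simulated training course.

    Per session: generate a (reduced) open-loop calibration run, fit the
    CSP-LDA decoder, then render scripted closed-loop EEG for each ramped
    exercise (the simulated subject holds each required state with 50%
    temporal margin) and evaluate the decoded stream.  Returns one
    :class:`SessionRecord` per session.
    """
    from .decoder import fit_decoder
    from .preprocess import bandpass_fir, epoch_and_window, reject_outlier_windows
    from .streaming import stream_decode
    from .synth import SynthEegConfig, generate_mi_session, generate_scripted_recording

    records = []
    for t in range(1, n_sessions + 1):
        cfg = SynthEegConfig(n_series=calibration_series,
                             trials_per_task=trials_per_task,
                             erd_depth=erd_depth, snr=snr,
                             seed=seed * 1009 + t)
        calib = generate_mi_session(cfg)
        ws, _ = reject_outlier_windows(epoch_and_window(bandpass_fir(calib)))
        model = fit_decoder(ws)
        record = SessionRecord(session_index=t)
        ex = ramped_exercise(t)
        for j in range(exercises_per_session):
            script = [(s, 1.5 * h) for s, h in ex.sequence]
            # the simulated subject holds the final state until time expires
            shortfall = ex.allotted_time - sum(d for _, d in script)
            if shortfall > 0:
                s_last, d_last = script[-1]
                script[-1] = (s_last, d_last + shortfall + 0.5)
            rec = generate_scripted_recording(
                script, config=cfg, seed=cfg.seed * 31 + j + 1)
            stream = stream_decode(rec, model)
            start = stream.times[np.searchsorted(stream.times, 2.0)]
            record.exercises.append(
                (ex, evaluate_exercise(stream, ex, start_time=start)))
        records.append(record)
    return records
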