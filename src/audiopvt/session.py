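"""Session engine: run a test against an abstract clock and input source.

The engine is simulation-first: responses arrive as a monotone stream of
timestamps (ms from session start) from an :class:`InputSource`, trials are
closed in schedule order, and every stimulus yields exactly one trial outcome
(true positive, false negative, or — for no-go — correct rejection or false
positive).  Extra button presses inside a trial window are logged as
additional false-positive records, so the number of button events always
equals ``n_true_positive + n_false_positive``.

Classification rules
--------------------
* go stimulus: the response time is ``timestamp - onset``.  A response faster
  than ``min_response_time`` is a false start (false positive) but leaves the
  trial open; the first response with
  ``min_response_time <= rt < window`` is the trial's true positive; any
  press after that is a spurious false positive.  A go trial with no press at
  all is a false negative (miss); a go trial with only false starts keeps its
  false-positive records and produces no separate miss record.
* no-go stimulus: any press in the window is a false positive (commission);
  no press is a correct rejection.  Correct rejections are bookkeeping
  records, not button events.

The response window closes at the next stimulus onset (or at the schedule's
session end for the last trial).  If the input stream ends before a window
closes, the session is saved as resumable rather than failed; resuming with
the remaining events reproduces an uninterrupted run exactly.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol

import numpy as np

from .exceptions import ConfigurationError
from .paradigms import StimulusEvent, StimulusKind, StimulusSchedule, TestConfig

__all__ = [
    "Classification",
    "ResponseRecord",
    "Clock",
    "SimulatedClock",
    "InputSource",
    "ScriptedInput",
    "SessionState",
    "classify_response",
    "run_session",
]

CHECKPOINT_VERSION = 1


class Classification(str, enum.Enum):
    TRUE_POSITIVE = "true_positive"
    FALSE_NEGATIVE = "false_negative"
    FALSE_POSITIVE = "false_positive"
    CORRECT_REJECTION = "correct_rejection"


@dataclass(frozen=True)
class ResponseRecord:
    """One classified response, miss, or correct rejection."""

    stimulus_index: int | None
    classification: Classification
    response_timestamp: float | None = None  # ms from session start
    response_time: float | None = None  # ms from stimulus onset
    stimulus_kind: StimulusKind | None = None

    def to_dict(self) -> dict:
        return {
            "stimulus_index": self.stimulus_index,
            "classification": self.classification.value,
            "response_timestamp": self.response_timestamp,
            "response_time": self.response_time,
            "stimulus_kind": None if self.stimulus_kind is None else self.stimulus_kind.value,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ResponseRecord":
        return cls(
            stimulus_index=d["stimulus_index"],
            classification=Classification(d["classification"]),
            response_timestamp=d["response_timestamp"],
            response_time=d["response_time"],
            stimulus_kind=None if d.get("stimulus_kind") is None else StimulusKind(d["stimulus_kind"]),
        )


class Clock(Protocol):
    """Monotonic millisecond clock."""

    def now(self) -> float: ...


class SimulatedClock:
    """Deterministic clock driven by the engine; sub-ms resolution, never reverses."""

    def __init__(self, start: float = 0.0) -> None:
        self._now = float(start)

    def now(self) -> float:
        return self._now

    def advance_to(self, t: float) -> None:
        if t > self._now:
            self._now = float(t)


class InputSource(Protocol):
    """Monotone stream of response timestamps with a validity horizon."""

    kind: str
    timestamps: np.ndarray
    horizon: float


@dataclass
class ScriptedInput:
    """Scripted response events: sorted timestamps in ms from session start.

    ``horizon`` is the time up to which the stream is known to be complete;
    trials whose window closes after the horizon cannot be adjudicated and
    leave the session resumable.  The on-disk script format is one timestamp
    (ms) per line.
    """

    timestamps: np.ndarray
    horizon: float = np.inf
    kind: str = "scripted"

    def __post_init__(self) -> None:
        ts = np.atleast_1d(np.asarray(self.timestamps, dtype=float))
        if ts.size and np.any(np.diff(ts) < 0):
            ts = np.sort(ts)
        self.timestamps = ts

    def to_file(self, path) -> Path:
        path = Path(path)
        path.write_text("".join(f"{t:.4f}\n" for t in self.timestamps), encoding="utf-8")
        return path

    @classmethod
    def from_file(cls, path, horizon: float = np.inf) -> "ScriptedInput":
        lines = Path(path).read_text(encoding="utf-8").split()
        return cls(np.array([float(x) for x in lines]), horizon=horizon)


@dataclass
class SessionState:
    """Mutable state of a (possibly interrupted) session."""

    config: TestConfig
    schedule: StimulusSchedule
    records: list[ResponseRecord] = field(default_factory=list)
    completed_trials: int = 0
    resumable: bool = False

    @property
    def progress(self) -> float:
        return self.completed_trials / self.config.repetitions

    @property
    def last_response_time(self) -> float | None:
        for rec in reversed(self.records):
            if rec.response_time is not None:
                return rec.response_time
        return None

    def to_json(self) -> str:
        return json.dumps(
            {
                "format": "audiopvt-session-checkpoint",
                "version": CHECKPOINT_VERSION,
                "config": self.config.to_dict(),
                "schedule": self.schedule.to_dict(),
                "records": [r.to_dict() for r in self.records],
                "completed_trials": self.completed_trials,
                "resumable": self.resumable,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SessionState":
        d = json.loads(text)
        if d.get("format") != "audiopvt-session-checkpoint":
            raise ConfigurationError("not a session checkpoint")
        if d.get("version") != CHECKPOINT_VERSION:
            raise ConfigurationError(f"unsupported checkpoint version {d.get('version')!r}")
        return cls(
            config=TestConfig.from_dict(d["config"]),
            schedule=StimulusSchedule.from_dict(d["schedule"]),
            records=[ResponseRecord.from_dict(r) for r in d["records"]],
            completed_trials=d["completed_trials"],
            resumable=d["resumable"],
        )

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(self.to_json(), encoding="utf-8")
        return path

    @classmethod
    def load(cls, path) -> "SessionState":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def classify_response(
    response_timestamp: float,
    stimulus: StimulusEvent,
    next_onset: float,
    config: TestConfig,
) -> tuple[Classification, float]:
    """Classify a single press landing in a stimulus's response window.

    Returns the classification and the response time
    ``response_timestamp - stimulus.onset``.  Go stimuli yield a true
    positive iff ``min_response_time <= rt < next_onset - onset`` and a false
    positive (false start) below the minimum response time; any press to a
    no-go stimulus is a false positive.
    """
    rt = response_timestamp - stimulus.onset
    if rt < 0 or response_timestamp >= next_onset:
        raise ValueError("response_timestamp outside this stimulus's window")
    if stimulus.kind is StimulusKind.NOGO:
        return Classification.FALSE_POSITIVE, rt
    if rt < config.min_response_time:
        return Classification.FALSE_POSITIVE, rt
    return Classification.TRUE_POSITIVE, rt


def run_session(
    schedule: StimulusSchedule,
    input_source: InputSource,
    clock: Clock | None = None,
    config: TestConfig | None = None,
    state: SessionState | None = None,
) -> SessionState:
    """Run (or resume) a session, closing trials in order.

    Parameters
    ----------
    schedule : StimulusSchedule
    input_source : InputSource
        Response-event stream.  Events earlier than the first open trial's
        onset (stale or pre-session) are ignored with a warning.
    clock : Clock, optional
        Advanced to each closed window's end; defaults to a fresh
        :class:`SimulatedClock`.
    config : TestConfig, optional
        Defaults to ``schedule.config``.
    state : SessionState, optional
        Resume from a previous interruption; prior records are conserved.
    """
    cfg = config if config is not None else schedule.config
    if clock is None:
        clock = SimulatedClock()
    if state is None:
        state = SessionState(config=cfg, schedule=schedule)
    elif state.completed_trials > len(schedule):
        raise ConfigurationError("checkpoint has more completed trials than the schedule")

    ts = np.asarray(input_source.timestamps, dtype=float)
    horizon = float(getattr(input_source, "horizon", np.inf))
    n = len(schedule)

    start = state.completed_trials
    ptr = 0
    if start < n:
        first_open_onset = schedule[start].onset
        ptr = int(np.searchsorted(ts, first_open_onset, side="left"))
        if ptr:
            what = "pre-session" if start == 0 else "stale (already-adjudicated)"
            warnings.warn(
                f"ignoring {ptr} {what} response event(s) before t={first_open_onset:.1f} ms",
                stacklevel=2,
            )

    for i in range(start, n):
        stim = schedule[i]
        w_end = schedule.window_end(i)
        if horizon < w_end:
            # Cannot confirm the window closed: save as resumable, not an error.
            state.resumable = True
            if hasattr(clock, "advance_to"):
                clock.advance_to(horizon)
            return state
        got_valid = False
        got_any = False
        while ptr < ts.size and ts[ptr] < w_end:
            t_resp = float(ts[ptr])
            ptr += 1
            got_any = True
            cls, rt = classify_response(t_resp, stim, w_end, cfg)
            if cls is Classification.TRUE_POSITIVE and got_valid:
                cls = Classification.FALSE_POSITIVE  # spurious extra press
            if cls is Classification.TRUE_POSITIVE:
                got_valid = True
            state.records.append(
                ResponseRecord(
                    stimulus_index=i,
                    classification=cls,
                    response_timestamp=t_resp,
                    response_time=rt,
                    stimulus_kind=stim.kind,
                )
            )
        if stim.kind is StimulusKind.NOGO:
            if not got_any:
                state.records.append(
                    ResponseRecord(
                        stimulus_index=i,
                        classification=Classification.CORRECT_REJECTION,
                        stimulus_kind=stim.kind,
                    )
                )
        elif not got_any:
            state.records.append(
                ResponseRecord(
                    stimulus_index=i,
                    classification=Classification.FALSE_NEGATIVE,
                    stimulus_kind=stim.kind,
                )
            )
        # A go trial with only false starts keeps its FP records (trial consumed).
        state.completed_trials = i + 1
        if hasattr(clock, "advance_to"):
            clock.advance_to(w_end)

    state.resumable = False
    return state
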