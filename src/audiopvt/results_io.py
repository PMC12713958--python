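"""Result-file read/write and condition-level aggregation.

Sessions are saved as comma-separated UTF-8 text, one row per response
record, under a filename derived from the subject and test ids
(``<subject>_<test>.csv``).  Existing files are never silently overwritten: a
``_v2``, ``_v3``, ... suffix is appended.  Response times and timestamps are
exported at 0.1 ms resolution and round-trip exactly at that resolution.

``aggregate_conditions`` turns groups of sessions (e.g. one group per
lighting condition and test time point) into a table of N, mean and SD of the
per-session mean response times.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ResultFileError
from .scoring import SessionSummary, summarize
from .session import Classification, ResponseRecord, SessionState
from .paradigms import StimulusKind

__all__ = [
    "ResultFile",
    "write_session",
    "read_session",
    "sanitize_identifier",
    "result_filename",
    "aggregate_conditions",
    "condition_contrast",
]

_COLUMNS = [
    "subject_id",
    "test_id",
    "trial_index",
    "stimulus_kind",
    "classification",
    "response_timestamp_ms",
    "response_time_ms",
]

_SAFE = re.compile(r"[A-Za-z0-9_-]")


@dataclass(frozen=True)
class ResultFile:
    subject_id: str
    test_id: str
    records: tuple[ResponseRecord, ...]

    def summary(self) -> SessionSummary:
        return summarize(self.records)


def sanitize_identifier(ident: str) -> str:
    """Restrict an id to [A-Za-z0-9_-]; any other character is percent-encoded."""
    out = []
    for ch in ident:
        if _SAFE.fullmatch(ch):
            out.append(ch)
        else:
            out.append("".join(f"%{b:02X}" for b in ch.encode("utf-8")))
    return "".join(out)


def result_filename(subject_id: str, test_id: str) -> str:
    return f"{sanitize_identifier(subject_id)}_{sanitize_identifier(test_id)}.csv"


def _round01(x: float | None) -> float:
    return math.nan if x is None else round(float(x), 1)


def write_session(state: SessionState, directory) -> Path:
    """Write one session's records; returns the path actually written.

    Raises :class:`ResultFileError` if the session has no trial outcomes or
    the directory is unwritable.
    """
    if not state.records:
        raise ResultFileError("session has no trial outcomes to save")
    directory = Path(directory)
    if not directory.is_dir():
        raise ResultFileError(f"not a writable directory: {directory}")
    base = result_filename(state.config.subject_id, state.config.test_id)
    path = directory / base
    version = 1
    while path.exists():
        version += 1
        path = directory / base.replace(".csv", f"_v{version}.csv")
    frame = pd.DataFrame(
        {
            "subject_id": state.config.subject_id,
            "test_id": state.config.test_id,
            "trial_index": [r.stimulus_index for r in state.records],
            "stimulus_kind": [None if r.stimulus_kind is None else r.stimulus_kind.value for r in state.records],
            "classification": [r.classification.value for r in state.records],
            "response_timestamp_ms": [_round01(r.response_timestamp) for r in state.records],
            "response_time_ms": [_round01(r.response_time) for r in state.records],
        },
        columns=_COLUMNS,
    )
    try:
        frame.to_csv(path, index=False, float_format="%.1f", encoding="utf-8")
    except OSError as exc:  # pragma: no cover - environment dependent
        raise ResultFileError(f"cannot write {path}: {exc}") from exc
    return path


def read_session(path) -> ResultFile:
    """Read a result file back into records (inverse of :func:`write_session`)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, encoding="utf-8")
    except (OSError, pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise ResultFileError(f"cannot read result file {path}: {exc}") from exc
    missing = set(_COLUMNS) - set(frame.columns)
    if missing:
        raise ResultFileError(f"result file {path} is missing column(s): {sorted(missing)}")
    records = []
    try:
        for row in frame.itertuples(index=False):
            records.append(
                ResponseRecord(
                    stimulus_index=None if pd.isna(row.trial_index) else int(row.trial_index),
                    classification=Classification(row.classification),
                    response_timestamp=None if pd.isna(row.response_timestamp_ms) else float(row.response_timestamp_ms),
                    response_time=None if pd.isna(row.response_time_ms) else float(row.response_time_ms),
                    stimulus_kind=None if pd.isna(row.stimulus_kind) else StimulusKind(row.stimulus_kind),
                )
            )
    except ValueError as exc:
        raise ResultFileError(f"result file {path} has malformed rows: {exc}") from exc
    if frame.empty:
        raise ResultFileError(f"result file {path} contains no records")
    subject = str(frame["subject_id"].iloc[0])
    test = str(frame["test_id"].iloc[0])
    return ResultFile(subject_id=subject, test_id=test, records=tuple(records))


def _session_mean_rt(entry) -> float:
    """Per-session mean RT from a number, SessionSummary, ResultFile, records, or path."""
    if isinstance(entry, (int, float, np.floating, np.integer)):
        return float(entry)
    if isinstance(entry, SessionSummary):
        return entry.rt_mean
    if isinstance(entry, ResultFile):
        return entry.summary().rt_mean
    if isinstance(entry, (str, Path)):
        return read_session(entry).summary().rt_mean
    # assume a sequence of ResponseRecord
    return summarize(entry).rt_mean


def aggregate_conditions(
    groups: Mapping[tuple, Sequence],
) -> pd.DataFrame:
    """Aggregate sessions into a per-(condition, time_point) table.

    Parameters
    ----------
    groups : mapping
        ``(condition, time_point) -> sequence of sessions``, where each
        session may be a per-session mean RT (number), a
        :class:`~audiopvt.scoring.SessionSummary`, a :class:`ResultFile`, a
        result-file path, or a record sequence.

    Returns
    -------
    pandas.DataFrame
        Indexed by (condition, time_point) with columns ``n``,
        ``mean_rt_ms``, ``sd_rt_ms``.  The group SD is over per-session
        means (n-1 denominator) and NaN for single-session groups.  Groups
        with no usable session are excluded with a warning.
    """
    rows = []
    for (condition, time_point), sessions in groups.items():
        means = np.array([_session_mean_rt(s) for s in sessions], dtype=float)
        means = np.sort(means[np.isfinite(means)])  # permutation-invariant reduction
        if means.size == 0:
            warnings.warn(
                f"group ({condition!r}, {time_point!r}) has no session with a mean RT; excluded",
                stacklevel=2,
            )
            continue
        rows.append(
            {
                "condition": condition,
                "time_point": time_point,
                "n": int(means.size),
                "mean_rt_ms": float(means.mean()),
                "sd_rt_ms": float(means.std(ddof=1)) if means.size > 1 else math.nan,
            }
        )
    table = pd.DataFrame(rows, columns=["condition", "time_point", "n", "mean_rt_ms", "sd_rt_ms"])
    return table.set_index(["condition", "time_point"])


def condition_contrast(table: pd.DataFrame, condition_a, condition_b, time_point) -> float:
    """Mean-RT difference (a - b) between two conditions at one time point, in ms."""
    a = table.loc[(condition_a, time_point), "mean_rt_ms"]
    b = table.loc[(condition_b, time_point), "mean_rt_ms"]
    return float(a - b)
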