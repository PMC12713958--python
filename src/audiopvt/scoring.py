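"""End-of-test counts and descriptive statistics.

``n_total`` counts button events (true positives + false positives); correct
rejections are bookkeeping, not presses.  Response-time statistics are
computed over true-positive response times only: false starts are excluded,
as are misses (which have no response time).  Quartiles use linear
interpolation between order statistics (the inclusive method); the standard
deviation uses the n-1 denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .session import Classification, ResponseRecord

__all__ = ["SessionSummary", "summarize", "response_speed"]


@dataclass(frozen=True)
class SessionSummary:
    """Counts and descriptive statistics of one session.

    Response-time fields are NaN when undefined (no true positives; SD also
    requires at least two).  ``mean_response_speed`` is the mean of
    ``1000 / rt_ms`` over true positives, in 1/s.
    """

    n_total: int
    n_true_positive: int
    n_false_negative: int
    n_false_positive: int
    n_correct_rejection: int
    rt_min: float
    rt_max: float
    rt_mean: float
    rt_sd: float
    rt_median: float
    rt_q1: float
    rt_q3: float
    mean_response_speed: float

    @property
    def has_rt_stats(self) -> bool:
        return self.n_true_positive > 0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def to_text(self) -> str:
        """Human-readable results block as shown at the end of a test."""

        def fmt(x: float) -> str:
            return "n/a" if not np.isfinite(x) else f"{x:.1f}"

        lines = [
            f"Total responses:      {self.n_total}",
            f"True positives:       {self.n_true_positive}",
            f"False negatives:      {self.n_false_negative}",
            f"False positives:      {self.n_false_positive}",
            f"Correct rejections:   {self.n_correct_rejection}",
            f"Response time min:    {fmt(self.rt_min)} ms",
            f"Response time max:    {fmt(self.rt_max)} ms",
            f"Response time mean:   {fmt(self.rt_mean)} ms",
            f"Response time SD:     {fmt(self.rt_sd)} ms",
            f"Response time median: {fmt(self.rt_median)} ms",
            f"Response time Q1:     {fmt(self.rt_q1)} ms",
            f"Response time Q3:     {fmt(self.rt_q3)} ms",
            f"Mean response speed:  "
            + ("n/a" if not np.isfinite(self.mean_response_speed) else f"{self.mean_response_speed:.3f} 1/s"),
        ]
        return "\n".join(lines)


def _tp_response_times(records: Iterable[ResponseRecord]) -> np.ndarray:
    return np.array(
        [
            r.response_time
            for r in records
            if r.classification is Classification.TRUE_POSITIVE and r.response_time is not None
        ],
        dtype=float,
    )


def summarize(records: Sequence[ResponseRecord]) -> SessionSummary:
    """Summarize a (complete or partial) session's records.

    An empty record set yields zero counts with all statistics NaN.
    """
    counts = {c: 0 for c in Classification}
    for r in records:
        counts[r.classification] += 1
    rts = _tp_response_times(records)
    if rts.size:
        q1, med, q3 = np.percentile(rts, [25.0, 50.0, 75.0], method="linear")
        stats = {
            "rt_min": float(rts.min()),
            "rt_max": float(rts.max()),
            "rt_mean": float(rts.mean()),
            "rt_sd": float(rts.std(ddof=1)) if rts.size > 1 else math.nan,
            "rt_median": float(med),
            "rt_q1": float(q1),
            "rt_q3": float(q3),
            "mean_response_speed": float(np.mean(1000.0 / rts)),
        }
    else:
        stats = {
            k: math.nan
            for k in (
                "rt_min", "rt_max", "rt_mean", "rt_sd",
                "rt_median", "rt_q1", "rt_q3", "mean_response_speed",
            )
        }
    return SessionSummary(
        n_total=counts[Classification.TRUE_POSITIVE] + counts[Classification.FALSE_POSITIVE],
        n_true_positive=counts[Classification.TRUE_POSITIVE],
        n_false_negative=counts[Classification.FALSE_NEGATIVE],
        n_false_positive=counts[Classification.FALSE_POSITIVE],
        n_correct_rejection=counts[Classification.CORRECT_REJECTION],
        **stats,
    )


def response_speed(records: Sequence[ResponseRecord]) -> float:
    """Mean response speed over true positives, ``mean(1000 / rt_ms)`` in 1/s.

    NaN when the session has no true positives.
    """
    rts = _tp_response_times(records)
    if not rts.size:
        return math.nan
    return float(np.mean(1000.0 / rts))
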