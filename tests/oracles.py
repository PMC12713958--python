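"""Independent brute-force oracles shared across test modules.

These re-derive results with plain loops and direct summation, deliberately
avoiding the library code paths they are used to check.
"""

from __future__ import annotations

import math


def replay_classifications(schedule, timestamps, config):
    """Re-derive every classification from the raw timestamp stream.

    Returns a list of ``(trial_index, classification_string)`` in trial/event
    order.  Rules: a press in a trial's window (onset up to the next onset,
    or the session end for the last trial) is a false positive if the trial
    is no-go, if the response time is below the minimum response time (false
    start), or if the trial already has a valid response; the first press at
    or above the minimum response time on a go trial is the true positive.
    A go trial with no press at all is a false negative; a no-go trial with
    no press is a correct rejection; a go trial with only false starts is
    consumed by them and yields no miss record.
    """
    ts = sorted(float(t) for t in timestamps)
    out = []
    n = len(schedule)
    for i in range(n):
        ev = schedule[i]
        w_end = schedule[i + 1].onset if i + 1 < n else schedule.session_end
        in_window = [t for t in ts if ev.onset <= t < w_end]
        got_valid = False
        for t in in_window:
            rt = t - ev.onset
            if ev.kind.value == "nogo":
                out.append((i, "false_positive"))
            elif got_valid or rt < config.min_response_time:
                out.append((i, "false_positive"))
            else:
                out.append((i, "true_positive"))
                got_valid = True
        if not in_window:
            out.append((i, "correct_rejection" if ev.kind.value == "nogo" else "false_negative"))
    return out


def quantiles_by_sorting(values, p):
    """Linear-interpolation (inclusive) quantile computed from first principles."""
    xs = sorted(values)
    n = len(xs)
    if n == 1:
        return xs[0]
    h = (n - 1) * p
    lo = math.floor(h)
    hi = math.ceil(h)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def paired_stats_by_summation(a, b):
    """Mean, sample SD, SEM and t of paired differences via direct summation."""
    diffs = [x - y for x, y in zip(a, b)]
    n = len(diffs)
    mean = sum(diffs) / n
    ss = sum((d - mean) ** 2 for d in diffs)
    sd = math.sqrt(ss / (n - 1))
    sem = sd / math.sqrt(n)
    t = mean / sem if sem > 0 else math.nan
    return mean, sd, sem, t
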