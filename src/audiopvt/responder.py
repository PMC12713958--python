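"""Synthetic responder: ex-Gaussian reaction times, lapses, commissions, false starts.

Human simple-RT distributions are well described by the ex-Gaussian law — the
sum of a Gaussian component (mu, sigma) capturing the central tendency and an
independent exponential tail (tau) capturing attentional slowing; its mean is
``mu + tau`` and its variance ``sigma**2 + tau**2``.  The responder turns a
stimulus schedule into a scripted response stream so every other module can
be exercised without hardware or participants.

Behavioural events:

* go stimulus: with probability ``1 - lapse_prob`` a response is emitted at
  ``onset + RT`` with RT ~ exGaussian truncated below at 0; otherwise the
  trial lapses (no response).
* no-go stimulus: answered (commission error) with probability
  ``nogo_commission_prob`` using the same RT law.
* false starts: a Poisson number of premature presses per session
  (``false_start_rate`` per minute of session time), each placed uniformly
  inside the premature window ``[onset, onset + min_response_time)`` of a
  uniformly chosen trial, so that every programmed false start is classified
  as a false start by the session engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError
from .paradigms import StimulusKind, StimulusSchedule
from .session import ScriptedInput

__all__ = ["ResponderModel", "sample_ex_gaussian", "simulate_responses"]


@dataclass(frozen=True)
class ResponderModel:
    """Parameters of the synthetic participant.

    mu, sigma, tau in ms; ``lapse_prob`` and ``nogo_commission_prob`` are
    per-trial probabilities; ``false_start_rate`` is premature presses per
    minute of session time.  Defaults describe an alert healthy adult on an
    auditory task: exGaussian mean 420 ms, SD ~103 ms, with rare lapses and
    commissions.
    """

    mu: float = 330.0
    sigma: float = 50.0
    tau: float = 90.0
    lapse_prob: float = 0.02
    false_start_rate: float = 0.2
    nogo_commission_prob: float = 0.05

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.tau < 0:
            raise ConfigurationError("sigma and tau must be >= 0 ms")
        if not 0.0 <= self.lapse_prob <= 1.0:
            raise ConfigurationError("lapse_prob must lie in [0, 1]")
        if not 0.0 <= self.nogo_commission_prob <= 1.0:
            raise ConfigurationError("nogo_commission_prob must lie in [0, 1]")
        if self.false_start_rate < 0:
            raise ConfigurationError("false_start_rate must be >= 0 per minute")

    @property
    def mean_rt(self) -> float:
        """Ex-Gaussian mean, mu + tau (ms), ignoring the truncation at 0."""
        return self.mu + self.tau

    @property
    def var_rt(self) -> float:
        """Ex-Gaussian variance, sigma**2 + tau**2 (ms**2)."""
        return self.sigma**2 + self.tau**2


def sample_ex_gaussian(
    rng: np.random.Generator, n: int, mu: float, sigma: float, tau: float
) -> np.ndarray:
    """Draw n ex-Gaussian variates (Gaussian + independent exponential), >= 0."""
    x = rng.normal(mu, sigma, size=n) if sigma > 0 else np.full(n, float(mu))
    if tau > 0:
        x = x + rng.exponential(tau, size=n)
    return np.maximum(x, 0.0)


def simulate_responses(
    schedule: StimulusSchedule,
    model: ResponderModel | None = None,
    seed: int | None = None,
) -> ScriptedInput:
    """Simulate one participant's button presses for a schedule.

    A single seed fans out to independent sub-streams for reaction times,
    lapses, commissions, and false starts, so e.g. changing the false-start
    rate does not perturb the reaction times.
    """
    if model is None:
        model = ResponderModel()
    rt_ss, lapse_ss, nogo_ss, fs_ss = np.random.SeedSequence(seed).spawn(4)
    rt_rng = np.random.default_rng(rt_ss)
    lapse_rng = np.random.default_rng(lapse_ss)
    nogo_rng = np.random.default_rng(nogo_ss)
    fs_rng = np.random.default_rng(fs_ss)

    timestamps: list[float] = []
    for ev in schedule:
        if ev.kind is StimulusKind.GO:
            if lapse_rng.random() < model.lapse_prob:
                continue
        else:
            if nogo_rng.random() >= model.nogo_commission_prob:
                continue
        rt = float(sample_ex_gaussian(rt_rng, 1, model.mu, model.sigma, model.tau)[0])
        timestamps.append(ev.onset + rt)

    min_rt = schedule.config.min_response_time
    if model.false_start_rate > 0 and min_rt > 0 and len(schedule) > 0:
        minutes = schedule.session_end / 60000.0
        n_fs = int(fs_rng.poisson(model.false_start_rate * minutes))
        if n_fs:
            trials = fs_rng.integers(0, len(schedule), size=n_fs)
            offsets = fs_rng.uniform(0.0, min_rt, size=n_fs)
            timestamps.extend(schedule[int(i)].onset + float(u) for i, u in zip(trials, offsets))

    return ScriptedInput(np.sort(np.asarray(timestamps, dtype=float)))
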