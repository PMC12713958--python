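"""Timing-validation analytics: quantization-error correction and agreement tests.

A software PVT is validated by simulating button presses at programmed
("expected") delays, letting the software report its own ("recorded") delays,
and observing the presses with an external recorder ("measured" delays).  A
recorder sampling every ``delta`` ms cannot see an event until the next
sample instant, which adds a systematic quantization error ``se``.  When
event times and the sampler share an integer-millisecond grid with a random
phase, ``se`` is discrete uniform on {0, 1, ..., delta-1} ms, with

    E(se)   = mean of {0..delta-1} = (delta - 1) / 2
    VAR(se) = population variance of that set = (delta**2 - 1) / 12

The measured delay decomposes as ``measured = true + E(se) + random error``,
so a corrected series is obtained by subtracting E(se) from the measured
values, and a corrected variance by subtracting VAR(se) from the measured
variance (variances of uncorrelated terms add).

Agreement between two series of paired delays is assessed with the
Bland-Altman method (mean difference, SD of differences, limits of agreement
at mean +/- 1.96 SD), a paired t-test, and an ordinary-least-squares
regression of the pairwise differences on the pairwise means to detect
proportional bias.

Recommended accuracy margins for PVT response timing are an absolute bias of
at most 5 ms with an SD of at most 10 ms; `PVT_BIAS_MARGIN_MS` and
`PVT_SD_MARGIN_MS` expose them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .exceptions import DomainError
from .paradigms import Paradigm, TestConfig, build_schedule
from .session import Classification, ScriptedInput, SimulatedClock, run_session

__all__ = [
    "PVT_BIAS_MARGIN_MS",
    "PVT_SD_MARGIN_MS",
    "QuantizerModel",
    "CorrectedSeries",
    "RegressionResult",
    "AgreementReport",
    "ValidationReport",
    "systematic_error_moments",
    "quantize",
    "correct_measurements",
    "bland_altman",
    "proportional_bias_regression",
    "one_sample_t",
    "run_validation_experiment",
    "EngineValidationResult",
    "run_engine_validation",
]

#: Recommended margins for PVT timing accuracy: |bias| <= 5 ms, SD <= 10 ms.
PVT_BIAS_MARGIN_MS = 5.0
PVT_SD_MARGIN_MS = 10.0

#: Limits-of-agreement multiplier (~95% of differences under normality).
LOA_MULTIPLIER = 1.96


def systematic_error_moments(delta: int) -> tuple[float, float]:
    """Mean and population variance of the quantization error for interval ``delta``.

    Enumerates the discrete-uniform support {0, 1, ..., delta-1} ms directly.
    For delta = 4 (a 250 Hz recorder): E = 1.5 ms, VAR = 1.25 ms**2.
    """
    if int(delta) != delta or delta < 1:
        raise DomainError("sampling interval must be an integer >= 1 ms")
    support = np.arange(int(delta), dtype=float)
    return float(support.mean()), float(support.var())


@dataclass(frozen=True)
class QuantizerModel:
    """An event recorder sampling every ``sampling_interval`` ms at a fixed phase.

    Grid instants are ``phase + k * sampling_interval``; an event is detected
    at the first instant at or after it occurs.
    """

    sampling_interval: float = 4.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.sampling_interval <= 0:
            raise DomainError("sampling_interval must be > 0 ms")
        if not 0.0 <= self.phase < self.sampling_interval:
            raise DomainError("phase must lie in [0, sampling_interval)")


def quantize(true_time, quantizer: QuantizerModel):
    """Detected time of an event: the smallest grid instant >= ``true_time``.

    Vectorized over ``true_time``; the offset ``measured - true`` lies in
    ``[0, sampling_interval)``.
    """
    t = np.asarray(true_time, dtype=float)
    if np.any(t < 0):
        raise DomainError("true_time must be >= 0 ms")
    delta = quantizer.sampling_interval
    k = np.ceil((t - quantizer.phase) / delta - 1e-12)
    out = quantizer.phase + k * delta
    return float(out) if np.isscalar(true_time) else out


@dataclass(frozen=True)
class CorrectedSeries:
    """A measured series with the systematic quantization error removed."""

    values: np.ndarray = field(repr=False)
    corrected_variance: float
    e_se: float
    var_se: float

    @property
    def corrected_mean(self) -> float:
        return float(np.mean(self.values))


def correct_measurements(measured, delta: int) -> CorrectedSeries:
    """Remove the expected quantization bias from a measured series.

    ``corrected = measured - E(se)`` elementwise; the corrected variance is
    the sample variance of the measured series minus VAR(se), floored at 0
    (with a warning) since a variance cannot be negative.
    """
    measured = np.asarray(measured, dtype=float)
    if measured.size == 0:
        raise DomainError("measured series must be non-empty")
    e_se, var_se = systematic_error_moments(delta)
    corrected = measured - e_se
    sample_var = float(measured.var(ddof=1)) if measured.size > 1 else 0.0
    corrected_var = sample_var - var_se
    if corrected_var < 0:
        warnings.warn(
            f"measured variance {sample_var:.4g} < VAR(se) {var_se:.4g}; "
            "corrected variance floored at 0",
            stacklevel=2,
        )
        corrected_var = 0.0
    return CorrectedSeries(values=corrected, corrected_variance=corrected_var, e_se=e_se, var_se=var_se)


@dataclass(frozen=True)
class RegressionResult:
    """OLS of paired differences on paired means (proportional-bias check)."""

    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    slope_t: float
    slope_p: float
    intercept_t: float
    intercept_p: float
    df: int

    @property
    def defined(self) -> bool:
        return math.isfinite(self.slope)


@dataclass(frozen=True)
class AgreementReport:
    """Bland-Altman agreement between two paired series (differences a - b)."""

    label: str
    n: int
    mean_diff: float
    sd_diff: float
    sem: float
    loa_low: float
    loa_high: float
    t_statistic: float
    df: int
    p_value: float
    regression: RegressionResult

    @property
    def t_defined(self) -> bool:
        return math.isfinite(self.t_statistic)

    def summary(self) -> str:
        t = f"t({self.df}) = {self.t_statistic:.4f}, p = {self.p_value:.4g}" if self.t_defined else "t undefined (zero SD)"
        return (
            f"{self.label}: mean diff {self.mean_diff:.2f} +/- {self.sem:.2f} ms (SEM), "
            f"LoA ({self.loa_low:.2f}, {self.loa_high:.2f}) ms, {t}; "
            f"proportional-bias slope {self.regression.slope:.4f} "
            f"(95% CI {self.regression.slope_ci[0]:.4f} to {self.regression.slope_ci[1]:.4f})"
        )

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n": self.n,
            "mean_diff_ms": self.mean_diff,
            "sd_diff_ms": self.sd_diff,
            "sem_ms": self.sem,
            "loa_low_ms": self.loa_low,
            "loa_high_ms": self.loa_high,
            "t": self.t_statistic,
            "df": self.df,
            "p": self.p_value,
            "slope": self.regression.slope,
            "slope_ci": list(self.regression.slope_ci),
            "slope_p": self.regression.slope_p,
            "intercept_ms": self.regression.intercept,
            "intercept_ci": list(self.regression.intercept_ci),
            "intercept_p": self.regression.intercept_p,
        }


def proportional_bias_regression(series_a, series_b) -> RegressionResult:
    """Regress differences (a - b) on means ((a + b) / 2) by OLS.

    A nonzero slope indicates proportional bias: the disagreement grows (or
    shrinks) with the magnitude of the quantity.  95% CIs use the t
    distribution with n - 2 degrees of freedom.  With no variance in the
    means the slope is undefined and returned as NaN.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise DomainError("series must have equal length")
    n = a.size
    if n < 3:
        raise DomainError("need at least 3 pairs for the regression")
    diffs = a - b
    means = 0.5 * (a + b)
    if np.ptp(means) == 0.0:
        nan = math.nan
        return RegressionResult(nan, nan, (nan, nan), (nan, nan), nan, nan, nan, nan, n - 2)
    model = sm.OLS(diffs, sm.add_constant(means)).fit()
    ci = model.conf_int(alpha=0.05)
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        intercept_ci=(float(ci[0][0]), float(ci[0][1])),
        slope_t=float(model.tvalues[1]),
        slope_p=float(model.pvalues[1]),
        intercept_t=float(model.tvalues[0]),
        intercept_p=float(model.pvalues[0]),
        df=int(model.df_resid),
    )


def bland_altman(series_a, series_b, label: str = "a vs. b") -> AgreementReport:
    """Bland-Altman agreement analysis of two paired series.

    Differences are ``a - b``; limits of agreement are
    ``mean_diff +/- 1.96 * sd_diff`` (sample SD); the paired t statistic is
    ``mean_diff / SEM`` with ``n - 1`` degrees of freedom and a two-sided
    p-value.  With zero SD (e.g. identical series) the t statistic is
    undefined and reported as NaN.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise DomainError("series must have equal length")
    n = a.size
    if n < 3:
        raise DomainError("need at least 3 pairs")
    diffs = a - b
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    sem = sd_diff / math.sqrt(n)
    if sem > 0:
        t_stat = mean_diff / sem
        p = 2.0 * float(scipy.stats.t.sf(abs(t_stat), n - 1))
    else:
        t_stat = math.nan
        p = math.nan
    return AgreementReport(
        label=label,
        n=n,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        sem=sem,
        loa_low=mean_diff - LOA_MULTIPLIER * sd_diff,
        loa_high=mean_diff + LOA_MULTIPLIER * sd_diff,
        t_statistic=t_stat,
        df=n - 1,
        p_value=p,
        regression=proportional_bias_regression(a, b),
    )


def one_sample_t(values, nominal: float) -> tuple[float, int, float]:
    """One-sample t-test of a series against a nominal value.

    Returns ``(t, df, p)`` with ``t = (mean - nominal) / (sd / sqrt(n))``,
    ``df = n - 1`` and a two-sided p; t is NaN when the sample SD is zero.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DomainError("need at least 2 values")
    sd = float(x.std(ddof=1))
    n = x.size
    if sd == 0:
        if float(x.mean()) == nominal:
            return 0.0, n - 1, math.nan
        return math.nan, n - 1, math.nan
    t = (float(x.mean()) - nominal) / (sd / math.sqrt(n))
    p = 2.0 * float(scipy.stats.t.sf(abs(t), n - 1))
    return t, n - 1, p


_COMPARISONS = [
    ("recorded_vs_expected", "recorded_ms", "expected_ms"),
    ("measured_vs_expected", "measured_ms", "expected_ms"),
    ("corrected_vs_expected", "corrected_ms", "expected_ms"),
    ("recorded_vs_measured", "recorded_ms", "measured_ms"),
    ("recorded_vs_corrected", "recorded_ms", "corrected_ms"),
]


@dataclass(frozen=True)
class ValidationReport:
    """Raw delay triples plus the five pairwise agreement analyses."""

    triples: pd.DataFrame = field(repr=False)
    comparisons: dict[str, AgreementReport]
    sampling_interval: int
    e_se: float
    var_se: float
    jitter_sd: float

    def to_csv(self, path) -> Path:
        path = Path(path)
        self.triples.to_csv(path, index=False)
        return path

    def to_dict(self) -> dict:
        return {
            "n": int(len(self.triples)),
            "sampling_interval_ms": self.sampling_interval,
            "e_se_ms": self.e_se,
            "var_se_ms2": self.var_se,
            "jitter_sd_ms": self.jitter_sd,
            "comparisons": {k: v.to_dict() for k, v in self.comparisons.items()},
        }

    def summary(self) -> str:
        head = (
            f"Timing-validation experiment: n = {len(self.triples)}, "
            f"sampling interval {self.sampling_interval} ms "
            f"(E(se) = {self.e_se} ms, VAR(se) = {self.var_se} ms^2), "
            f"software jitter SD {self.jitter_sd} ms"
        )
        return "\n".join([head] + [r.summary() for r in self.comparisons.values()])


def run_validation_experiment(
    n_trials: int = 1000,
    delay_min: float = 300.0,
    delay_max: float = 990.0,
    delay_step: float = 10.0,
    sampling_interval: int = 4,
    jitter_sd: float = 0.0,
    seed: int | None = None,
) -> ValidationReport:
    """Simulate the full measurement chain and analyze every pairwise agreement.

    Expected delays cycle deterministically over the grid
    ``delay_min : delay_step : delay_max``; the software-recorded delay adds
    zero-mean Gaussian jitter of SD ``jitter_sd`` (default 0: the software
    layer is exact); the externally measured delay quantizes the true delay
    with an independent integer sampler phase per trial, uniform on
    {0..sampling_interval-1} ms, which realizes the discrete-uniform
    systematic-error model; the corrected series subtracts E(se) from the
    measured one.

    Returns a :class:`ValidationReport` with the raw
    expected/recorded/measured/corrected series and the five pairwise
    Bland-Altman / t-test / proportional-bias analyses.
    """
    if delay_max < delay_min or delay_step <= 0:
        raise DomainError("need delay_min <= delay_max and delay_step > 0")
    if n_trials < 3:
        raise DomainError("need at least 3 trials")
    grid = np.arange(delay_min, delay_max + 0.5 * delay_step, delay_step, dtype=float)
    expected = np.tile(grid, int(np.ceil(n_trials / grid.size)))[:n_trials]

    jitter_ss, phase_ss = np.random.SeedSequence(seed).spawn(2)
    if jitter_sd > 0:
        recorded = expected + np.random.default_rng(jitter_ss).normal(0.0, jitter_sd, size=n_trials)
    else:
        recorded = expected.copy()

    e_se, var_se = systematic_error_moments(sampling_interval)
    phases = np.random.default_rng(phase_ss).integers(0, sampling_interval, size=n_trials).astype(float)
    # ceil to each trial's own grid: phase + k*delta >= expected
    k = np.ceil((expected - phases) / sampling_interval - 1e-12)
    measured = phases + k * sampling_interval
    corrected = correct_measurements(measured, sampling_interval).values

    triples = pd.DataFrame(
        {
            "trial": np.arange(n_trials),
            "expected_ms": expected,
            "recorded_ms": recorded,
            "measured_ms": measured,
            "corrected_ms": corrected,
        }
    )
    comparisons = {
        name: bland_altman(triples[col_a].to_numpy(), triples[col_b].to_numpy(), label=name.replace("_", " "))
        for name, col_a, col_b in _COMPARISONS
    }
    return ValidationReport(
        triples=triples,
        comparisons=comparisons,
        sampling_interval=int(sampling_interval),
        e_se=e_se,
        var_se=var_se,
        jitter_sd=float(jitter_sd),
    )


@dataclass(frozen=True)
class EngineValidationResult:
    """Programmed vs. session-engine-recorded response delays."""

    expected: np.ndarray = field(repr=False)
    recorded: np.ndarray = field(repr=False)

    @property
    def bias(self) -> float:
        """Mean of recorded - expected, in ms."""
        return float(np.mean(self.recorded - self.expected))

    @property
    def sd(self) -> float:
        return float(np.std(self.recorded - self.expected, ddof=1))

    @property
    def within_pvt_margins(self) -> bool:
        return abs(self.bias) <= PVT_BIAS_MARGIN_MS and self.sd <= PVT_SD_MARGIN_MS


def run_engine_validation(
    n_trials: int = 1000,
    delay_min: float = 300.0,
    delay_max: float = 990.0,
    delay_step: float = 10.0,
    seed: int | None = None,
) -> EngineValidationResult:
    """End-to-end software-timing check through the actual session engine.

    Builds a simple-RT schedule of ``n_trials`` stimuli, scripts one button
    press per stimulus at ``onset + delay`` with the programmed delays
    cycling over the grid, runs the session against a simulated monotonic
    clock, and compares the engine-recorded response times with the
    programmed delays.  The scripted chain is exact, so the software layer
    must add zero bias by construction.
    """
    config = TestConfig(
        paradigm=Paradigm.SIMPLE_RT,
        repetitions=int(n_trials),
        min_delay=1000.0,
        max_delay=10000.0,
        min_response_time=100.0,
        subject_id="SIM",
        test_id="VALIDATION",
    )
    schedule = build_schedule(config, seed=seed)
    grid = np.arange(delay_min, delay_max + 0.5 * delay_step, delay_step, dtype=float)
    expected = np.tile(grid, int(np.ceil(n_trials / grid.size)))[:n_trials]
    presses = schedule.onsets + expected
    state = run_session(schedule, ScriptedInput(presses), clock=SimulatedClock(), config=config)
    recorded = np.array(
        [r.response_time for r in state.records if r.classification is Classification.TRUE_POSITIVE],
        dtype=float,
    )
    if recorded.size != n_trials:
        raise AssertionError(
            f"engine validation expected {n_trials} true positives, got {recorded.size}"
        )
    return EngineValidationResult(expected=expected, recorded=recorded)
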