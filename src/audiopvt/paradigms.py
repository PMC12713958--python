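"""Stimulus scheduling and tone synthesis for auditory psychomotor vigilance testing.

Two stimulus paradigms are implemented:

``simple_rt``
    An unprepared simple reaction-time test probing tonic central-nervous
    activation: a single tone is presented repeatedly and the inter-stimulus
    interval (ISI) is drawn uniformly at random between a configurable minimum
    and maximum delay, so the participant cannot anticipate the next stimulus.

``go_no_go``
    A selective-attention / response-inhibition variant with two tones
    presented at a fixed ISI (the configured minimum delay).  The participant
    responds to the *go* tone and withholds the response to the *no-go* tone;
    the no-go tone is four times the go frequency (two octaves up) and shares
    the go tone's duration.

All times are real-valued milliseconds from session start.  The ISI is
anchored at stimulus *offset*: the drawn delay separates the end of one tone
from the onset of the next, so long tones can never overlap the next trial.
"""

from __future__ import annotations

import dataclasses
import enum
import wave
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DomainError

__all__ = [
    "Paradigm",
    "StimulusKind",
    "TestConfig",
    "StimulusEvent",
    "StimulusSchedule",
    "ToneWaveform",
    "build_schedule",
    "derive_nogo_frequency",
    "synthesize_tone",
    "expected_session_duration",
    "NOGO_FREQUENCY_RATIO",
]

#: The no-go tone is the quadruple of the go tone (two octaves above it).
NOGO_FREQUENCY_RATIO = 4.0

#: Default go tone: 440 Hz (A4 pitch standard), 150 ms.
DEFAULT_TONE_FREQUENCY_HZ = 440.0
DEFAULT_TONE_DURATION_MS = 150.0


class Paradigm(str, enum.Enum):
    """Implemented stimulus paradigms."""

    SIMPLE_RT = "simple_rt"
    GO_NO_GO = "go_no_go"


class StimulusKind(str, enum.Enum):
    """Whether the participant should respond (go) or withhold (no-go)."""

    GO = "go"
    NOGO = "nogo"


@dataclass(frozen=True)
class TestConfig:
    """All user-settable parameters of a test run.

    Parameters
    ----------
    paradigm : Paradigm or str
        ``simple_rt`` or ``go_no_go``.
    tone_frequency : float
        Go-tone frequency in Hz, > 0.
    tone_duration : float
        Tone duration in ms, > 0 (both tones share it in go/no-go).
    tone_volume : float
        Peak amplitude as a fraction of full scale, in [0, 1].
    min_delay, max_delay : float
        Bounds of the ISI in ms (offset-to-onset).  In go/no-go the ISI is
        fixed at ``min_delay``.
    repetitions : int
        Number of stimuli in a complete session, >= 1.
    min_response_time : float
        Responses faster than this many ms after stimulus onset are
        physiologically implausible and classified as false positives
        (false starts).
    nogo_fraction : float
        Expected proportion of no-go stimuli in go/no-go, in [0, 1).
    seed : int or None
        Default seed for schedule construction; ``build_schedule`` may
        override it.
    subject_id, test_id : str
        Identifiers used to derive result filenames.
    """

    paradigm: Paradigm = Paradigm.SIMPLE_RT
    tone_frequency: float = DEFAULT_TONE_FREQUENCY_HZ
    tone_duration: float = DEFAULT_TONE_DURATION_MS
    tone_volume: float = 0.8
    min_delay: float = 1000.0
    max_delay: float = 10000.0
    repetitions: int = 110
    min_response_time: float = 100.0
    nogo_fraction: float = 0.25
    seed: int | None = None
    subject_id: str = "S00"
    test_id: str = "T00"

    def __post_init__(self) -> None:
        object.__setattr__(self, "paradigm", Paradigm(self.paradigm))
        if self.tone_frequency <= 0:
            raise ConfigurationError("tone_frequency must be > 0 Hz")
        if self.tone_duration <= 0:
            raise ConfigurationError("tone_duration must be > 0 ms")
        if not 0.0 <= self.tone_volume <= 1.0:
            raise ConfigurationError("tone_volume must lie in [0, 1]")
        if self.min_delay < 0:
            raise ConfigurationError("min_delay must be >= 0 ms")
        if self.max_delay < self.min_delay:
            raise ConfigurationError("max_delay must be >= min_delay")
        if int(self.repetitions) != self.repetitions or self.repetitions < 1:
            raise ConfigurationError("repetitions must be a positive integer")
        object.__setattr__(self, "repetitions", int(self.repetitions))
        if self.min_response_time < 0:
            raise ConfigurationError("min_response_time must be >= 0 ms")
        if not 0.0 <= self.nogo_fraction < 1.0:
            raise ConfigurationError("nogo_fraction must lie in [0, 1)")

    @property
    def nogo_frequency(self) -> float:
        """Frequency of the no-go tone (4 x go frequency)."""
        return derive_nogo_frequency(self.tone_frequency)

    def replace(self, **changes) -> "TestConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["paradigm"] = self.paradigm.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TestConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration field(s): {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class StimulusEvent:
    """One scheduled stimulus."""

    index: int
    onset: float  # ms from session start
    kind: StimulusKind
    frequency: float  # Hz
    duration: float  # ms

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered stimulus events plus the session-end time.

    ``session_end`` closes the response window of the last trial; it sits one
    nominal ISI after the last tone's offset.
    """

    config: TestConfig
    events: tuple[StimulusEvent, ...]
    session_end: float

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[StimulusEvent]:
        return iter(self.events)

    def __getitem__(self, i: int) -> StimulusEvent:
        return self.events[i]

    @property
    def onsets(self) -> np.ndarray:
        return np.array([e.onset for e in self.events])

    @property
    def n_go(self) -> int:
        return sum(e.kind is StimulusKind.GO for e in self.events)

    @property
    def n_nogo(self) -> int:
        return sum(e.kind is StimulusKind.NOGO for e in self.events)

    def window_end(self, i: int) -> float:
        """End of trial i's response window: the next onset, or session end."""
        if i + 1 < len(self.events):
            return self.events[i + 1].onset
        return self.session_end

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [e.index for e in self.events],
                "onset_ms": [e.onset for e in self.events],
                "kind": [e.kind.value for e in self.events],
                "frequency_hz": [e.frequency for e in self.events],
                "duration_ms": [e.duration for e in self.events],
            }
        )

    def to_csv(self, path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "session_end": self.session_end,
            "events": [
                {
                    "index": e.index,
                    "onset": e.onset,
                    "kind": e.kind.value,
                    "frequency": e.frequency,
                    "duration": e.duration,
                }
                for e in self.events
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSchedule":
        return cls(
            config=TestConfig.from_dict(d["config"]),
            events=tuple(
                StimulusEvent(
                    index=e["index"],
                    onset=e["onset"],
                    kind=StimulusKind(e["kind"]),
                    frequency=e["frequency"],
                    duration=e["duration"],
                )
                for e in d["events"]
            ),
            session_end=d["session_end"],
        )


def derive_nogo_frequency(go_frequency: float) -> float:
    """No-go tone frequency: the quadruple of the go tone (e.g. 440 -> 1760 Hz)."""
    if go_frequency <= 0:
        raise DomainError("go_frequency must be > 0 Hz")
    return NOGO_FREQUENCY_RATIO * go_frequency


def build_schedule(config: TestConfig, seed: int | None = None) -> StimulusSchedule:
    """Build the stimulus schedule for one session.

    The ISI is drawn independently per trial from a continuous uniform law on
    ``[min_delay, max_delay]`` (simple RT) or fixed at ``min_delay``
    (go/no-go).  A single seed fans out to independent sub-streams for ISI
    draws and go/no-go assignment, so changing ``nogo_fraction`` never
    perturbs the ISIs.

    Parameters
    ----------
    config : TestConfig
    seed : int, optional
        Overrides ``config.seed``.  Two calls with identical config and seed
        produce identical schedules.
    """
    if seed is None:
        seed = config.seed
    isi_ss, kind_ss = np.random.SeedSequence(seed).spawn(2)
    isi_rng = np.random.default_rng(isi_ss)
    kind_rng = np.random.default_rng(kind_ss)

    go_no_go = config.paradigm is Paradigm.GO_NO_GO
    nogo_freq = config.nogo_frequency
    events: list[StimulusEvent] = []
    t = 0.0
    for i in range(config.repetitions):
        if go_no_go:
            delay = config.min_delay
            is_nogo = bool(kind_rng.random() < config.nogo_fraction)
        else:
            delay = float(isi_rng.uniform(config.min_delay, config.max_delay))
            is_nogo = False
        onset = t + delay
        events.append(
            StimulusEvent(
                index=i,
                onset=onset,
                kind=StimulusKind.NOGO if is_nogo else StimulusKind.GO,
                frequency=nogo_freq if is_nogo else config.tone_frequency,
                duration=config.tone_duration,
            )
        )
        t = onset + config.tone_duration
    session_end = t + (config.min_delay if go_no_go else config.max_delay)
    return StimulusSchedule(config=config, events=tuple(events), session_end=session_end)


def expected_session_duration(config: TestConfig) -> float:
    """Expected session duration in ms under the uniform ISI law.

    ``repetitions * (tone_duration + E[ISI])`` with ``E[ISI]`` equal to
    ``(min_delay + max_delay) / 2`` for simple RT and ``min_delay`` for
    go/no-go.
    """
    if config.paradigm is Paradigm.GO_NO_GO:
        mean_isi = config.min_delay
    else:
        mean_isi = 0.5 * (config.min_delay + config.max_delay)
    return config.repetitions * (config.tone_duration + mean_isi)


@dataclass(frozen=True)
class ToneWaveform:
    """A synthesized tone: mono samples in [-1, 1] at a fixed sample rate."""

    sample_rate: float
    samples: np.ndarray = field(repr=False)

    @property
    def duration_ms(self) -> float:
        return 1000.0 * len(self.samples) / self.sample_rate

    def to_wav(self, path) -> Path:
        """Write the tone as a 16-bit PCM mono WAV file."""
        path = Path(path)
        pcm = np.clip(np.round(self.samples * 32767.0), -32768, 32767).astype("<i2")
        with wave.open(str(path), "wb") as fh:
            fh.setnchannels(1)
            fh.setsampwidth(2)
            fh.setframerate(int(round(self.sample_rate)))
            fh.writeframes(pcm.tobytes())
        return path


def synthesize_tone(
    frequency: float,
    duration: float,
    volume: float = 1.0,
    sample_rate: float = 44100.0,
    ramp: float = 5.0,
) -> ToneWaveform:
    """Synthesize a sine tone with raised-cosine onset/offset ramps.

    Parameters
    ----------
    frequency : float
        Tone frequency in Hz; must lie below the Nyquist rate.
    duration : float
        Duration in ms.
    volume : float
        Peak amplitude in [0, 1].
    sample_rate : float
        Samples per second (default 44.1 kHz).
    ramp : float
        On/off ramp length in ms (default 5 ms) to avoid audible clicks; each
        ramp is capped at half the tone length.
    """
    if frequency <= 0:
        raise DomainError("frequency must be > 0 Hz")
    if frequency >= sample_rate / 2.0:
        raise DomainError(
            f"frequency {frequency} Hz is at or above the Nyquist rate "
            f"({sample_rate / 2.0} Hz)"
        )
    if duration <= 0:
        raise DomainError("duration must be > 0 ms")
    if not 0.0 <= volume <= 1.0:
        raise DomainError("volume must lie in [0, 1]")

    n = int(round(duration / 1000.0 * sample_rate))
    t = np.arange(n) / sample_rate
    x = volume * np.sin(2.0 * np.pi * frequency * t)
    n_ramp = min(int(round(ramp / 1000.0 * sample_rate)), n // 2)
    if n_ramp > 0:
        env = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        x[:n_ramp] *= env
        x[-n_ramp:] *= env[::-1]
    return ToneWaveform(sample_rate=sample_rate, samples=x)
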