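"""Exception hierarchy for audiopvt."""


class AudioPVTError(Exception):
    """Base class for all audiopvt errors."""


class ConfigurationError(AudioPVTError, ValueError):
    """A test configuration violates its constraints (e.g. max_delay < min_delay)."""


class DomainError(AudioPVTError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class ResultFileError(AudioPVTError):
    """A session result file is missing, malformed, or cannot be written."""
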