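"""Exception hierarchy shared across the package."""


class MixtoxError(Exception):
    """Base class for all package errors."""


class ConfigError(MixtoxError, ValueError):
    """Invalid configuration; the message names the offending field."""


class ValidationError(MixtoxError, ValueError):
    """Malformed or inconsistent input data."""


class DegenerateDataError(MixtoxError, ValueError):
    """Data degenerate for the requested statistic (e.g. zero variance)."""


class StageError(MixtoxError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
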