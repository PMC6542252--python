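"""Exception hierarchy."""


class RhythmkitError(Exception):
    """Base class for all rhythmkit errors."""


class EventLogError(RhythmkitError):
    """Raised for unreadable or (in strict mode) malformed event logs."""

    def __init__(self, message: str, problems: list[tuple[int, str]] | None = None):
        super().__init__(message)
        #: list of (line number, description) for malformed records
        self.problems = problems or []


class ConfigError(RhythmkitError):
    """Raised for invalid or unparseable configuration."""


class SimulationError(RhythmkitError):
    """Raised when simulation parameters are inconsistent."""
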