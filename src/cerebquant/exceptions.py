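"""Exception types shared across the package."""


class CerebquantError(Exception):
    """Base class for package errors."""


class ParameterError(CerebquantError, ValueError):
    """A simulation or analysis parameter violates its documented constraints."""


class UndefinedStatisticError(CerebquantError):
    """The requested statistic is undefined for this input (too few events,
    zero denominator, no complex spikes, ...). Carries an explicit status
    string so callers can report *why* rather than a bare failure."""

    def __init__(self, status: str, message: str | None = None):
        self.status = status
        super().__init__(message or status)


class CalibrationError(CerebquantError):
    """Session-level normalization is impossible (e.g. no US-containing
    trial to define the size of a full blink)."""


class SchemaError(CerebquantError, ValueError):
    """A tabular input does not match its declared schema."""


class SWCError(CerebquantError, ValueError):
    """A reconstruction file is malformed; the message names the line."""
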