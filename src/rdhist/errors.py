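"""Exception hierarchy for the rdhist pipeline.

Every error raised on bad user input derives from :class:`RdhistError`
so callers (and the CLI) can catch a single base class.
"""


class RdhistError(Exception):
    """Base class for all rdhist errors."""


class ConfigurationError(RdhistError):
    """A configuration field violates its invariant; names the field."""


class ParseError(RdhistError):
    """A file could not be parsed; carries a 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(RdhistError):
    """An argument violates an operation precondition."""


class NormalizationError(RdhistError):
    """Size factors could not be computed."""


class DesignError(RdhistError):
    """The sample design cannot support the requested test."""


class SamplingError(RdhistError):
    """A random gene-set could not be drawn (universe too small)."""


class InsufficientSamplesError(RdhistError):
    """Too few samples remain after subtype/condition filtering."""


class IntegrityError(RdhistError):
    """The packaged catalog fixture failed its count checks."""
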