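"""Exception hierarchy.

Everything derives from :class:`TrustfuseError` so callers can catch the
package's failures with one clause; the numeric-validation subclasses also
derive from :class:`ValueError` for idiomatic use.
"""


class TrustfuseError(Exception):
    """Base class for all errors raised by trustfuse."""


class InvalidArgumentError(TrustfuseError, ValueError):
    """An argument violates a documented precondition."""


class InvalidSamplingRateError(InvalidArgumentError):
    """Sampling rate too low for the requested filtering."""


class DegenerateInputError(TrustfuseError, ValueError):
    """Input is formally valid but statistically degenerate (e.g. zero variance)."""


class AlignmentError(TrustfuseError, ValueError):
    """Responses could not be aligned to the event timeline."""


class FieldValidationError(TrustfuseError, ValueError):
    """A record field is out of its documented range."""


class ParseError(TrustfuseError, ValueError):
    """A file could not be parsed into the expected record type."""


class UndefinedStatisticError(TrustfuseError, ValueError):
    """The requested statistic is undefined for this input (e.g. p_e = 1 for kappa)."""
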