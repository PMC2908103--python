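"""Exception hierarchy for pmtcal.

All package-specific failures derive from :class:`PmtcalError` so callers
(and the CLI) can catch one base class.
"""


class PmtcalError(Exception):
    """Base class for all pmtcal errors."""


class DomainError(PmtcalError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class BelowBackgroundError(DomainError):
    """A signal intensity at or below the autofluorescence floor cannot be
    inverted to a surface density."""


class InsufficientDataError(PmtcalError, ValueError):
    """Too few usable observations (or degenerate design) to fit the model."""


class AllBackgroundError(InsufficientDataError):
    """Every observation sits below twice the background estimate: the
    dataset carries no information about B or a."""


class FormatError(PmtcalError, ValueError):
    """A file does not conform to its declared format."""


class LayoutValidationError(PmtcalError, ValueError):
    """A parsed layout violates structural invariants (e.g. duplicate
    spot coordinates)."""
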