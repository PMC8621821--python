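"""Exception hierarchy for vitdfort.

All errors derive from :class:`VitdfortError` so callers can catch the
package's failures with a single except clause; each also subclasses the
closest builtin (ValueError/KeyError) for duck-typed handling.
"""


class VitdfortError(Exception):
    """Base class for all vitdfort errors."""


class InvalidStudyError(VitdfortError, ValueError):
    """A study effect has non-positive or inconsistent RR/CI values."""


class InsufficientStudiesError(VitdfortError, ValueError):
    """Fewer studies than the operation requires."""


class UnknownLabelError(VitdfortError, KeyError):
    """A study label was not found in the study set."""


class ExtrapolationError(VitdfortError, ValueError):
    """Requested dose lies outside the evidence (anchor) range."""


class CoverageError(VitdfortError, ValueError):
    """A mortality stratum cannot be resolved in the life table."""


class ConfigurationError(VitdfortError, ValueError):
    """The scenario or cost configuration is incomplete or inconsistent."""


class DomainError(VitdfortError, ValueError):
    """A numeric argument lies outside its mathematical domain."""
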