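"""Exception hierarchy shared across the package.

Every user-facing failure mode maps onto one of these classes so that the
CLI can translate any :class:`EmtquadError` into exit code 2.
"""


class EmtquadError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EmtquadError):
    """A configuration field is missing, malformed, or out of range."""


class FormatError(EmtquadError):
    """An input table violates its format contract (coordinates included)."""


class MissingFeatureError(EmtquadError):
    """A requested gene/isoform id is absent from the expression matrix."""


class InsufficientCohortError(EmtquadError):
    """Too few samples (or too few values) for the requested analysis."""


class DegenerateInputError(EmtquadError):
    """Input is degenerate: zero variance, single level, collinear, ..."""


class NonEstimableError(EmtquadError):
    """The estimand is not identifiable from the data (e.g. zero events)."""
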