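"""Exception hierarchy.

Every error raised by this package derives from :class:`WillisError`, so
callers (in particular the CLI) can distinguish pipeline failures from
programming errors.
"""


class WillisError(Exception):
    """Base class for all package errors."""


class SchemaError(WillisError):
    """Input table is missing a mandatory column or has an unusable layout."""


class IntegrityError(WillisError):
    """Input data violate a structural invariant (duplicate ids, bad proband count)."""


class MissingDataError(WillisError):
    """A diameter required for classification is missing."""


class ClassificationError(WillisError):
    """A vessel configuration falls outside the supported variant categories."""


class UsageError(WillisError):
    """An operation was called with arguments outside its contract."""


class MatchingError(WillisError):
    """No admissible comparison family exists for an index family."""


class FitError(WillisError):
    """The conditional likelihood has no informative data to fit."""


class AggregationError(WillisError):
    """Too few converged iterations to summarise an outcome."""


class ParameterError(WillisError):
    """Simulation parameters are infeasible."""


class GenerationError(WillisError):
    """Synthetic diameter generation failed to invert the classification rules."""
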