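"""Exception hierarchy.

Every input-contract violation raises a distinct, named error so callers
(and the CLI) can report exactly what is wrong with a survey table.
"""


class SkerrydivError(Exception):
    """Base class for all package errors."""


class ValidationError(SkerrydivError):
    """A table or domain object violates its contract."""


class MissingColumnError(ValidationError):
    """A required column is absent from an input table."""


class DuplicateLabelError(ValidationError):
    """A square id or species name occurs more than once."""


class PresenceValueError(ValidationError):
    """An occurrence entry is not 0 or 1."""


class MissingTraitError(ValidationError):
    """A species in the occurrence matrix has no trait record."""


class VocabularyError(ValidationError):
    """A classification / red-list value is outside its closed vocabulary."""


class NoRetainedSquaresError(SkerrydivError):
    """Filtering removed every square; records cannot be reassigned."""


class UndefinedPairError(SkerrydivError):
    """Sorensen dissimilarity is undefined when both squares are empty."""


class ZeroVarianceError(SkerrydivError):
    """A statistic requires variation that the input does not have."""


class ConvergenceError(SkerrydivError):
    """Profile likelihood could not be maximised."""
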