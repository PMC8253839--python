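"""Exception hierarchy shared across the package.

Every contract violation raises a subclass of :class:`SceneSemError` so that
callers (and the CLI) can distinguish contract errors (exit code 2) from I/O
failures (exit code 3).
"""


class SceneSemError(Exception):
    """Base class for all package-specific errors."""


class MalformedLabelError(SceneSemError):
    """An object label is empty or otherwise unusable."""


class InvalidMapError(SceneSemError):
    """A label map is cyclic or not idempotent."""


class UnknownLabelError(SceneSemError):
    """Requested labels are absent from a vocabulary or embedding table."""


class FormatError(SceneSemError):
    """A text file does not conform to its declared format."""


class AlignmentError(SceneSemError):
    """Two containers that must share category/voxel order do not."""


class UndefinedDistanceError(SceneSemError):
    """Pearson distance is undefined (constant vector)."""


class CoverageError(SceneSemError):
    """A category is not covered by the selected runs."""


class RankError(SceneSemError):
    """Requested more components than the data's rank supports."""


class SingularDesignError(SceneSemError):
    """A regression design matrix is rank deficient on a training fold."""


class NoTrainableDataError(SceneSemError):
    """The corpus contains no scene with at least two in-vocabulary labels."""


class DomainError(SceneSemError):
    """A numeric argument is outside its valid domain."""


class ContractError(SceneSemError):
    """Inputs violate a cross-call contract (e.g. mismatched permutation streams)."""


class SpecError(SceneSemError):
    """A synthetic-data specification is internally inconsistent."""
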