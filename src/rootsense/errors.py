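"""Exception hierarchy shared across the pipeline stages."""


class RootsenseError(Exception):
    """Base class for all package-specific errors."""


class DomainError(RootsenseError, ValueError):
    """A scalar argument is outside its documented domain."""


class InputError(RootsenseError, ValueError):
    """A structured input (image, mask, box list) violates a precondition."""


class EmptyInputError(InputError):
    """An operation that needs at least one element received none."""


class DegenerateInputError(InputError):
    """Clustering input has fewer distinct points than clusters."""


class PlacementError(RootsenseError, RuntimeError):
    """Synthetic scene objects could not be placed without overlap."""


class SchemaError(RootsenseError, ValueError):
    """A tabular file is missing required columns or has bad values."""


class AnnotationFormatError(RootsenseError, ValueError):
    """A bounding-box annotation line is malformed or out of range."""


class ConfigurationError(RootsenseError, ValueError):
    """An unknown provider, model family, or invalid hyperparameter."""


class TrainingError(RootsenseError, RuntimeError):
    """Model training diverged or otherwise failed."""


class UndefinedMetricError(RootsenseError, ValueError):
    """A metric is undefined for the given inputs (e.g. zero-variance y)."""
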