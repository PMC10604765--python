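"""Exception hierarchy shared across the pipeline.

Validation and parameter problems map to CLI exit code 2, data-quality
problems (e.g. too few confident samples near a wall) to exit code 3.
"""


class SpeckleflowError(Exception):
    """Base class for all package errors."""


class ValidationError(SpeckleflowError, ValueError):
    """A container or configuration violates an invariant."""


class ParameterError(SpeckleflowError, ValueError):
    """A scalar argument is out of its admissible range."""


class DomainError(SpeckleflowError, ValueError):
    """Coordinates fall outside the field of view."""


class QualityError(SpeckleflowError, RuntimeError):
    """The data are too unreliable to produce the requested quantity."""


class InsufficientDataError(QualityError):
    """Fewer valid samples than the operation needs."""
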