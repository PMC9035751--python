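"""Package-specific exception types."""


class ClemTargetError(Exception):
    """Base class for all package errors."""


class PackingError(ClemTargetError):
    """Requested organelles could not be placed without overlap."""


class SceneBoundsError(ClemTargetError):
    """Scene content does not fit the requested render grid."""


class SubstrateNotFoundError(ClemTargetError):
    """No substrate edge detected in a SEM frame."""


class AlignmentError(ClemTargetError):
    """Stack alignment failed (e.g. too many undetectable frames)."""


class ResampleError(ClemTargetError):
    """Requested voxel size is not achievable by integer binning."""


class RotationAmbiguousError(ClemTargetError):
    """MIP rotation search found no unique angle."""


class InsufficientCorrespondencesError(ClemTargetError):
    """Fewer matched fiducial pairs than the transform model needs."""


class DegenerateGeometryError(ClemTargetError):
    """Landmark geometry does not constrain the transform."""


class TargetNotHeldOutError(ClemTargetError):
    """A blind target was part of the transform fit."""


class PromptTooSmallError(ClemTargetError):
    """A contour prompt covers too few pixels for thresholding."""
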