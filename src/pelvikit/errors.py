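"""Exception hierarchy for pelvikit.

All package-specific failures derive from :class:`PelvikitError` so callers
can catch one base class at the CLI boundary.
"""


class PelvikitError(Exception):
    """Base class for all pelvikit errors."""


class DegenerateLandmarksError(PelvikitError, ValueError):
    """Two landmarks coincide, so a reference line is undefined."""


class InvalidThresholdError(PelvikitError, ValueError):
    """Diagnosis threshold outside the open interval (0, 90) degrees."""


class LengthMismatchError(PelvikitError, ValueError):
    """Paired prediction/truth sequences have different lengths."""


class EmptyInputError(PelvikitError, ValueError):
    """An operation requiring at least one element received none."""


class UnknownLabelError(PelvikitError, ValueError):
    """Class label is not one of {'normal', 'ddh'}."""


class GeometryOutOfBoundsError(PelvikitError, ValueError):
    """Phantom geometry does not fit inside the requested canvas."""


class SchemaError(PelvikitError, ValueError):
    """COCO annotation file violates the expected schema."""

    def __init__(self, message: str, image_id=None):
        super().__init__(message)
        self.image_id = image_id


class NoComponentsError(PelvikitError, ValueError):
    """Segmentation found no foreground components."""


class MissingSideError(PelvikitError, ValueError):
    """A required per-side mask (e.g. an ilium) is absent."""


class ShapeMismatchError(PelvikitError, ValueError):
    """Masks or images have inconsistent raster shapes."""


class BackendError(PelvikitError, ValueError):
    """Unknown or unusable detector backend."""


class PipelineStageError(PelvikitError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
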