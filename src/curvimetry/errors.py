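"""Exception hierarchy for the curvature-measurement tool.

Every failure mode named in the stage contracts maps to one exception
class so callers (and the CLI) can report which stage of the chain
failed and why.
"""


class CurvimetryError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(CurvimetryError, ValueError):
    """A phantom specification violates one of its invariants.

    The message names the offending field.
    """


class OutOfRangeError(CurvimetryError, ValueError):
    """A camera tilt lies outside the modeled capture range."""


class PlacementError(CurvimetryError, ValueError):
    """A requested degradation hole would touch the mask boundary."""


class EmptyMaskError(CurvimetryError, ValueError):
    """A mask operation received a mask with no foreground pixels."""


class InvalidBoxError(CurvimetryError, ValueError):
    """A bounding box is malformed or lies fully outside the image."""


class DegenerateShapeError(CurvimetryError):
    """The shape has fewer than four admissible corners (e.g. a disc)."""


class NoLinesError(CurvimetryError):
    """No Hough accumulator peak exceeded the vote threshold."""


class SelectionFailureError(CurvimetryError):
    """One of the two edge regions received no candidate line."""


class DegenerateImageError(CurvimetryError, ValueError):
    """An image has no intensity contrast to segment."""


class LocalizationFailureError(CurvimetryError):
    """The detector returned no bounding box for the image."""


class SplitError(CurvimetryError, ValueError):
    """Cross-validation folds cannot be formed from the given groups."""


class PipelineStageError(CurvimetryError):
    """Wraps a downstream failure with the name of the pipeline stage.

    Attributes
    ----------
    stage : str
        Name of the stage that failed (``"localize"``, ``"segment"``,
        ``"postprocess"``, ``"corners"``, ``"lines"``, ``"select"``).
    cause : Exception
        The original exception.
    """

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
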