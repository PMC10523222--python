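"""Exception hierarchy for the squat-posture pipeline.

Every stage raises a subclass of :class:`SquatCheckError` so callers (and the
CLI) can report which stage failed and on which file/frame.
"""


class SquatCheckError(Exception):
    """Base class for all pipeline errors."""


class PoseParseError(SquatCheckError):
    """Keypoint JSON is malformed; message names the file and frame."""


class EmptyInputError(SquatCheckError):
    """A sequence or dataset with zero frames/items where at least one is required."""


class DataQualityError(SquatCheckError):
    """A required joint is missing in too many frames for reliable interpolation."""


class DegeneratePoseError(SquatCheckError):
    """Reference pose unusable, e.g. zero torso length."""


class SchemaError(SquatCheckError):
    """Input tensor/sequence does not match the expected joint set or channel count."""


class TooShortError(SquatCheckError):
    """Sequence shorter than the minimum temporal length for the requested operation."""


class ValidationError(SquatCheckError):
    """Invalid configuration or parameter value."""
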