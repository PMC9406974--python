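"""Exception hierarchy.

Validation failures (bad parameters, malformed files, violated invariants)
derive from :class:`ValidationError`; the CLI maps them to exit code 2.
Runtime processing failures derive from :class:`ProcessingError` (exit 1).
"""


class StrokeperfError(Exception):
    """Base class for all package errors."""


class ValidationError(StrokeperfError):
    """Invalid input: bad parameter, malformed file, violated precondition."""


class ProcessingError(StrokeperfError):
    """A pipeline stage failed on otherwise valid input."""


class ParameterError(ValidationError):
    pass


class DimensionError(ValidationError):
    pass


class GeometryError(ValidationError):
    pass


class FormatError(ValidationError):
    pass


class UnitError(ValidationError):
    pass


class SampleSizeError(ValidationError):
    pass


class JoinError(ValidationError):
    pass


class MaskingError(ProcessingError):
    pass


class BolusDetectionError(ProcessingError):
    pass


class AIFDetectionError(ProcessingError):
    pass


class FitError(ProcessingError):
    pass


class DeconvolutionError(ProcessingError):
    pass


class MapError(ProcessingError):
    pass


class SegmentationError(ProcessingError):
    pass


class DegenerateDataError(ProcessingError):
    pass


class StageError(ProcessingError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
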