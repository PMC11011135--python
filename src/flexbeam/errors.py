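"""Exception hierarchy shared across the package."""


class FlexbeamError(Exception):
    """Base class for all flexbeam errors."""


class ValidationError(FlexbeamError, ValueError):
    """An argument violates a documented precondition."""


class GeometryError(ValidationError):
    """Requested array geometry is infeasible (e.g. radius too small)."""


class DegenerateInputError(FlexbeamError, ValueError):
    """Input is structurally valid but degenerate (e.g. all-zero data)."""


class NoPeakError(FlexbeamError):
    """No peak response could be found inside the gated window."""


class UndefinedMetricError(FlexbeamError):
    """A metric is undefined for the given input (e.g. profile never
    falls below half maximum)."""


class FormatError(FlexbeamError, ValueError):
    """A container file is missing required metadata."""


class PipelineStageError(FlexbeamError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
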