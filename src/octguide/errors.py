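"""Exception hierarchy for the pipeline stages."""


class OctGuideError(Exception):
    """Base class for all pipeline errors."""


class PhantomConfigError(OctGuideError):
    """Invalid phantom specification (overlapping fiducials, buried canal...)."""


class FieldOfViewError(OctGuideError):
    """A fiducial falls outside the OCT field of view."""


class InsufficientFiducialsError(OctGuideError):
    """Fewer than 3 fiducials available; registration is impossible."""


class AmbiguousMatchError(OctGuideError):
    """Two fiducial labelings explain the distance pattern equally well."""


class DegenerateConfigurationError(OctGuideError):
    """Collinear fiducials: the rigid fit is not unique."""


class SegmentationError(OctGuideError):
    """Canal segmentation produced an empty mask."""


class PlanningError(OctGuideError):
    """Target planning failed (empty silhouette, bad view direction...)."""


class PipelineStageError(OctGuideError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
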