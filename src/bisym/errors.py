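"""Exception hierarchy shared by all pipeline stages."""


class BisymError(Exception):
    """Base class for all package errors."""


class MeshIOError(BisymError):
    """File could not be read or written."""


class MeshFormatError(BisymError):
    """File parsed but does not contain a usable triangle mesh."""


class GeometryError(BisymError):
    """Geometric precondition violated (degenerate input, empty crop, ...)."""


class ParameterError(BisymError):
    """Invalid parameter value."""


class AmbiguityError(GeometryError):
    """Axis direction cannot be decided without a hint."""


class PipelineStageError(BisymError):
    """Wraps a failure with the name of the pipeline stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}': {cause}")
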