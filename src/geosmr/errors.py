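"""Exception hierarchy shared across the pipeline stages."""


class GeoSMRError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(GeoSMRError):
    """A configuration violates its invariants."""


class InvalidInputError(GeoSMRError):
    """An input table or array violates a stage precondition."""


class NumericalError(GeoSMRError):
    """A numerical routine failed (e.g. covariance not positive definite)."""


class PipelineStageError(GeoSMRError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
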