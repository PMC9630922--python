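"""Exception types shared across the pipeline."""


class CordMaskVarError(Exception):
    """Base class for all package errors."""


class GeometryError(CordMaskVarError):
    """A phantom or shift would place the cord outside the image grid."""


class UndefinedMetricError(CordMaskVarError):
    """A metric is undefined on the requested scope (empty region,
    zero mean, degenerate variance, too few observations)."""


class DesignError(CordMaskVarError):
    """A statistical design is incomplete or degenerate."""


class StageError(CordMaskVarError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
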