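"""Exception hierarchy for the vascsig pipeline."""


class VascsigError(Exception):
    """Base class for all vascsig errors."""


class DataError(VascsigError):
    """Malformed, inconsistent, or out-of-range input data."""


class ConfigurationError(VascsigError):
    """Invalid parameter or configuration value."""


class ModelError(VascsigError):
    """Degenerate statistical model (collinear design, zero residual df, ...)."""


class EstimationError(VascsigError):
    """A survival estimate or test could not be computed from the records given."""


class SearchError(VascsigError):
    """No admissible candidate in an optimization (e.g. score cutoff search)."""


class PipelineStageError(VascsigError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
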