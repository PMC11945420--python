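"""Exception hierarchy shared across the pipeline stages."""


class PipelineError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(PipelineError):
    """An invalid simulation, model, or run configuration."""


class SchemaError(PipelineError):
    """A required column or key is missing from an input table."""


class DataError(PipelineError):
    """Input data violate a precondition of an operation."""


class StageError(PipelineError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
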