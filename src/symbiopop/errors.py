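"""Package-wide exception types."""


class SymbiopopError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SymbiopopError):
    """Invalid configuration values (bad ranges, missing categories, unknown keys)."""


class SimulationError(SymbiopopError):
    """Errors raised while generating synthetic data (e.g. variant-site collisions)."""


class PipelineError(SymbiopopError):
    """Errors raised by pipeline-level checks (e.g. empty retained sample set)."""


class StageError(SymbiopopError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
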