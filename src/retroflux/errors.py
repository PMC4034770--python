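"""Exception hierarchy for the retroflux pipeline."""


class RetrofluxError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(RetrofluxError):
    """Invalid simulation or analysis configuration."""


class NormalizationError(RetrofluxError):
    """A gel column cannot be normalized (e.g. zero total intensity)."""


class ConsistencyError(RetrofluxError):
    """Inputs contradict each other (e.g. a spot outside the declared universe)."""


class PipelineError(RetrofluxError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")
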