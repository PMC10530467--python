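"""Exception types shared across the pipeline."""


class FamvarnetError(Exception):
    """Base class for all package errors."""


class InputError(FamvarnetError):
    """A malformed or inconsistent input file or record (fatal)."""


class ConfigError(FamvarnetError):
    """An invalid parameter or run configuration."""


class PipelineError(FamvarnetError):
    """A stage of the orchestrated pipeline failed."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
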