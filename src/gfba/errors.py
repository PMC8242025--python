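"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3,
StageError -> 4.
"""


class GfbaError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(GfbaError):
    """Invalid configuration or parameter values."""

    exit_code = 2


class DataError(GfbaError):
    """Malformed, inconsistent, or missing data."""

    exit_code = 3


class StageError(GfbaError):
    """A pipeline stage failed; carries the stage name."""

    exit_code = 4

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
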