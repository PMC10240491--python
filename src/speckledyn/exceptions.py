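"""Exception hierarchy shared across the package."""


class SpeckledynError(Exception):
    """Base class for all package errors."""


class ConfigError(SpeckledynError):
    """Invalid or inconsistent configuration."""


class SchemaError(SpeckledynError):
    """A file does not conform to the frame-stack schema.

    Carries the list of missing or invalid fields so callers can report
    exactly what is wrong with a foreign file.
    """

    def __init__(self, message, missing=()):
        super().__init__(message)
        self.missing = tuple(missing)


class DegenerateInputError(SpeckledynError):
    """Input carries no usable signal (e.g. zero mean intensity in a bin)."""


class FitError(SpeckledynError):
    """A model fit failed to converge; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class StageError(SpeckledynError):
    """A pipeline stage failed; names the stage and its inputs."""

    def __init__(self, stage, message):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
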