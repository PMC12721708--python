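"""Exception types shared across the pipeline."""


class CaplastError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(CaplastError, ValueError):
    """An input violated a stated precondition (non-finite config value,
    overlapping movement bouts, disc outside the frame, ...)."""


class NoEvokedWindowError(CaplastError):
    """No supra-threshold run of the event probability profile exists at or
    after stimulus onset — the session has no detectable evoked window."""


class SchemaError(CaplastError):
    """A session/raster file is missing a required dataset or attribute."""

    def __init__(self, field: str, message: str | None = None):
        self.field = field
        super().__init__(message or f"missing or invalid field: {field!r}")
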