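"""Exception hierarchy shared across the package."""


class GenoprioError(Exception):
    """Base class for all package errors."""


class VcfParseError(GenoprioError):
    """Raised when a VCF file cannot be parsed; message names the line."""


class PedParseError(GenoprioError):
    """Raised for malformed PED files."""


class ConfigError(GenoprioError):
    """Raised for invalid run configuration values."""


class StoreValidationError(GenoprioError):
    """Raised when an evidence table violates a load-time invariant."""


class GenerationError(GenoprioError):
    """Raised when a synthetic fixture request is contradictory or unsupported."""


class PipelineError(GenoprioError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
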