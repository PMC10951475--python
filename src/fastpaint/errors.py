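"""Exception hierarchy shared across the pipeline."""


class FastPaintError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FastPaintError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(FastPaintError):
    """In-memory data violates a contract (coordinates, frames, shapes)."""


class RegistrationError(ValidationError):
    """Images that must be pixel-registered have mismatched dimensions."""


class DatasetTooSmallError(ValidationError):
    """A training split would fall below the minimum pair count."""


class ConfigError(FastPaintError):
    """An invalid configuration value."""
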