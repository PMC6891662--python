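"""Exception hierarchy shared across the package."""


class ImmunoquantError(Exception):
    """Base class for all package-specific errors."""


class DomainError(ImmunoquantError, ValueError):
    """An input value lies outside its documented domain."""


class ConfigError(ImmunoquantError, ValueError):
    """Invalid configuration value or distribution specification."""


class SizingError(ImmunoquantError, ValueError):
    """Requested geometry does not fit on the requested canvas."""


class PlacementError(ImmunoquantError, RuntimeError):
    """Objects could not be placed without overlap within bounded retries."""


class NoBeadError(ImmunoquantError, RuntimeError):
    """No bead-sized connected component found in an image."""


class FormatError(ImmunoquantError, ValueError):
    """Unsupported image format or bit depth."""


class SchemaError(ImmunoquantError, ValueError):
    """A delimited table does not match its declared schema."""
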