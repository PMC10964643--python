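"""Exception hierarchy shared across the package."""


class SwpkitError(Exception):
    """Base class for all package errors."""


class SchemaError(SwpkitError):
    """A file or config violates the on-disk schema (missing keys, bad enums)."""


class FormatError(SwpkitError):
    """A file parses but its contents are malformed (e.g. non-uniform time grid)."""


class DataError(SwpkitError):
    """Values are invalid for the requested computation (NaN, empty group, ...)."""


class DegenerateSignalError(DataError):
    """A trace is constant or flat where variation is required."""


class LengthError(SwpkitError):
    """A trace is longer than the configured fixed length."""


class ConfigError(SwpkitError):
    """A run configuration is invalid or contains unknown keys."""
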