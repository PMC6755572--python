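"""Exception types shared across the package."""


class GknnError(Exception):
    """Base class for package-specific errors."""


class SchemaError(GknnError, ValueError):
    """A configured column or field is missing from an input file."""


class DataError(GknnError, ValueError):
    """A record violates a data contract (range, missing source calls, ...)."""


class FingerprintError(GknnError, ValueError):
    """A structure could not be fingerprinted, or fingerprints are incompatible."""


class ConfigError(GknnError, ValueError):
    """An invalid configuration value (unknown mode, bad grid, ...)."""
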