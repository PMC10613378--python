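"""Exception types shared across the package."""


class PeernetError(Exception):
    """Base class for package errors."""


class ConfigurationError(PeernetError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class SchemaError(PeernetError, ValueError):
    """An input table does not match the expected schema."""


class StructuralError(PeernetError, ValueError):
    """Inputs are individually valid but mutually inconsistent."""
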