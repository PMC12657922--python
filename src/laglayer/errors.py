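"""Exception hierarchy shared across the package."""


class LagLayerError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(LagLayerError):
    """An input violated a documented precondition."""


class SchemaError(LagLayerError):
    """A file on disk does not match the expected bundle schema."""
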