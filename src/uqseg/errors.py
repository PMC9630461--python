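"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A configuration value is invalid; the message names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field '{field}': {message}")


class ShapeError(ValueError):
    """An array has an incompatible shape."""


class DatasetIOError(OSError):
    """A dataset directory is malformed (e.g. an image without a mask)."""
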