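"""Exception types shared across the package."""


class DataValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


class ConfigError(ValueError):
    """Raised when a run configuration is malformed."""
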