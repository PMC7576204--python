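"""Package-wide exception types."""


class ValidationError(ValueError):
    """Input data or arguments violate a documented contract."""


class ConfigurationError(ValueError):
    """A configuration object is internally inconsistent."""


class TrainingError(RuntimeError):
    """Optimization failed (e.g. divergent loss)."""
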