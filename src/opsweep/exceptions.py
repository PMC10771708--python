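"""Package exception hierarchy."""


class OpSweepError(Exception):
    """Base class for all package errors."""


class SchemaError(OpSweepError):
    """A required column is missing or a cell cannot be parsed."""


class ValidationError(OpSweepError):
    """A record violates a domain invariant."""

    def __init__(self, message: str, violations=None):
        super().__init__(message)
        self.violations = violations or []


class ConfigurationError(OpSweepError):
    """Inconsistent generator / pipeline configuration."""


class DegenerateFeatureError(OpSweepError):
    """A feature is constant where variation is required."""

    def __init__(self, feature: str):
        super().__init__(f"feature {feature!r} is constant on the training split")
        self.feature = feature
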