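"""Exception types shared across the package."""


class LasegError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(LasegError):
    """Raised when data violates a documented invariant or precondition."""


class ConfigurationError(LasegError):
    """Raised for invalid or inconsistent configuration."""


class UndefinedMetricError(LasegError):
    """Raised when a metric is undefined for the given inputs
    (e.g. Hausdorff distance against an empty mask)."""
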