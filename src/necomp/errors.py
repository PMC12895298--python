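"""Exception types shared across the package."""


class NecompError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(NecompError, ValueError):
    """Raised when an operation receives arguments outside its domain."""


class TreeError(NecompError, ValueError):
    """Raised for malformed, non-ultrametric or otherwise unusable trees."""


class ModelError(NecompError, ValueError):
    """Raised when a regression model cannot be fit (collinearity, non-PD
    covariance, optimizer failure)."""
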