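"""Exception hierarchy shared across the package."""


class FluorbindError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FluorbindError, ValueError):
    """Raised when input data violate a documented invariant."""


class FitError(FluorbindError, RuntimeError):
    """Raised when a regression cannot be performed on the given data."""
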