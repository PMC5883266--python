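"""Exception types shared across the package."""


class DoseshiftError(Exception):
    """Base class for all doseshift errors."""


class ValidationError(DoseshiftError, ValueError):
    """Raised when input data violate a structural invariant."""


class DomainError(DoseshiftError, ValueError):
    """Raised when an argument is outside the mathematical domain of an operation."""
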