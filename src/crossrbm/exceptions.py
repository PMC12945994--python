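"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: usage errors -> 2 (click), ValidationError
and DimensionError -> 3, NumericError -> 4.
"""


class CrossRBMError(Exception):
    """Base class for all package errors."""


class DimensionError(CrossRBMError, ValueError):
    """Array shapes are mutually inconsistent."""


class ValidationError(CrossRBMError, ValueError):
    """Input values violate a documented precondition or schema."""


class CapabilityError(CrossRBMError, RuntimeError):
    """The exact/enumeration path was requested beyond its feasible size."""


class NumericError(CrossRBMError, ArithmeticError):
    """A computation produced NaN/Inf and was aborted."""
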