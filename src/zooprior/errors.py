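"""Exception and warning types shared across the package."""

from __future__ import annotations


class ZooPriorError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(ZooPriorError):
    """One or more input violations.

    Validation is total: every violation found in an input is collected and
    reported together, never just the first.

    Parameters
    ----------
    errors : list of str
        Human-readable descriptions, one per violation.
    """

    def __init__(self, errors):
        if isinstance(errors, str):
            errors = [errors]
        self.errors = list(errors)
        super().__init__("\n".join(f"- {e}" for e in self.errors))


class ConvergenceError(ZooPriorError):
    """Iterative priority derivation failed to converge."""

    def __init__(self, message: str, residual: float):
        self.residual = residual
        super().__init__(f"{message} (residual={residual:.3e})")


class RecommendationWarning(UserWarning):
    """Input is valid but outside a recommended range (e.g. criteria count
    outside 5-9, participants outside 6-12, diseases outside 15-30, more
    than 5 ordinal categories). Promoted to an error in strict mode."""


class ConsistencyWarning(UserWarning):
    """A pairwise-comparison matrix has consistency ratio above 0.1."""


class ScaleRangeWarning(UserWarning):
    """A pairwise judgment ratio lies outside the Saaty range [1/9, 9]."""
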