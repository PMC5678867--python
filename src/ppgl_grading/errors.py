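"""Exception types shared across the package.

The scoring engines refuse to guess: a histology field that is ``None``
raises :class:`MissingDataError` naming the field, because silently
treating a missing feature as absent would bias every score downward.
"""


class PPGLError(Exception):
    """Base class for all package errors."""


class MissingDataError(PPGLError):
    """A required input field is missing."""

    def __init__(self, field: str, detail: str = ""):
        self.field = field
        msg = f"missing required field: {field!r}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class DomainError(PPGLError):
    """A value lies outside its documented domain."""


class ConfigError(PPGLError):
    """Invalid configuration (weights, probabilities, thresholds)."""


class SchemaError(PPGLError):
    """A cohort file does not match the documented column schema."""


class DegenerateTableError(PPGLError):
    """A contingency table has a zero margin and admits no test."""


class ConvergenceError(PPGLError):
    """An iterative fit failed to converge (e.g. monotone Cox likelihood)."""
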