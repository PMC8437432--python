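"""Exception hierarchy shared across the package."""

__all__ = [
    "AHbA1cError",
    "InputError",
    "FormatError",
    "EligibilityError",
    "NumericalError",
]


class AHbA1cError(Exception):
    """Base class for package-specific errors."""


class InputError(AHbA1cError, ValueError):
    """Invalid argument or malformed in-memory input."""


class FormatError(AHbA1cError, ValueError):
    """A delimited input file could not be parsed."""


class EligibilityError(AHbA1cError):
    """Data do not meet an eligibility gate (coverage, history, variability).

    Callers performing cohort processing catch this and flag the subject or
    section instead of crashing.
    """


class NumericalError(AHbA1cError):
    """An integration or optimisation step produced non-finite values."""
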