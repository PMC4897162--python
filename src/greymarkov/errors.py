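"""Exception hierarchy shared across the package."""


class GreyMarkovError(Exception):
    """Base class for all package errors."""


class SeriesValidationError(GreyMarkovError, ValueError):
    """Raised when an input series violates the model's requirements.

    Carries the 1-based data row number where the problem was found,
    when one can be identified.
    """

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class FixtureNotFoundError(GreyMarkovError, KeyError):
    """Raised when a named packaged dataset does not exist."""


class DegenerateTrendError(GreyMarkovError, ValueError):
    """Raised when the development coefficient is (numerically) zero and an
    operation that requires a genuine exponential trend was requested."""


class CorrectionError(GreyMarkovError, ValueError):
    """Raised when a residual correction would drive a fitted value <= 0."""
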