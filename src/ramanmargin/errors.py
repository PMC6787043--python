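"""Exception hierarchy for the Raman margin-assessment pipeline.

Every error raised on bad user input derives from :class:`RamanError`, so
callers (and the CLI) can catch one base class.  Errors are deliberately
specific: a descending wavenumber axis, a malformed row, and an empty file
are different failure modes and are reported as such.
"""


class RamanError(Exception):
    """Base class for all pipeline errors."""


class AxisOrderError(RamanError):
    """Raman-shift axis is not strictly increasing."""


class AxisMismatchError(RamanError):
    """Two spectra (or a spectrum and a vector) are not on the same axis."""


class SpectrumParseError(RamanError):
    """A spectrum file contains a malformed row; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class EmptyInputError(RamanError):
    """No data where at least one record is required."""


class CoverageError(RamanError):
    """A spectrum does not cover enough of the target instrument axis."""


class StageError(RamanError):
    """Operation applied at the wrong processing stage (stages are monotone)."""


class WindowError(RamanError):
    """Invalid running-window parameter (even, too small, or too large)."""


class ShapeError(RamanError):
    """Vector length mismatch between a spectrum and a companion array."""


class DegenerateSpectrumError(RamanError):
    """Normalization region integral is zero or negative."""


class InsufficientSupportError(RamanError):
    """Too few baseline windows / anchor points to fit a spline."""


class InsufficientSampleError(RamanError):
    """Fewer spectra than the statistic requires."""


class BandCoverageError(RamanError):
    """A band window falls outside the spectrum axis support."""


class SchemaError(RamanError):
    """Feature-table / score-table columns do not match the fitted model."""


class ProfileMismatchError(RamanError):
    """Spectra and models were built for different instrument profiles."""


class LabelError(RamanError):
    """Unknown tissue-class label."""


class ConfigError(RamanError):
    """Run configuration failed validation; names the offending field."""
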