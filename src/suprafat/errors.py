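"""Exception hierarchy.

Every anticipated failure mode maps to a distinct subclass of
:class:`SuprafatError` so callers (and the CLI) can distinguish bad input
from degenerate data from numerical failure.
"""


class SuprafatError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SuprafatError):
    """A file could be opened but does not carry the expected content."""


class UnsupportedInputError(SuprafatError):
    """Valid file, but a variant this package deliberately does not handle."""


class AlignmentError(SuprafatError):
    """Mask and slice grids (or polygon inputs) do not line up."""


class DegenerateRoiError(SuprafatError):
    """ROI too small or empty for a meaningful intensity analysis."""


class IncompleteStackError(SuprafatError):
    """A 3-slice stack is missing an image or a mask for the requested region."""


class MissingPeakError(SuprafatError):
    """No spectral peak found above the noise floor in a search window."""

    def __init__(self, peak: str, message: str | None = None):
        self.peak = peak
        super().__init__(message or f"no {peak} peak found above the noise floor")


class FitFailureError(SuprafatError):
    """Nonlinear least squares did not converge."""


class UndefinedRatioError(SuprafatError):
    """Fat/water ratio undefined (water amplitude at or below zero)."""


class UndefinedStatisticError(SuprafatError):
    """A statistic is undefined on this input (e.g. zero variance)."""


class InputError(SuprafatError):
    """Structurally invalid input (mixed subjects, out-of-range grade, ...)."""


class GenerationError(SuprafatError):
    """A synthetic-data request cannot be satisfied with the given geometry."""
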