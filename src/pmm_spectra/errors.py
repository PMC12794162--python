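"""Exception hierarchy.

Errors are grouped so that callers (and the CLI exit codes) can distinguish
bad configuration, invalid data, degenerate geometry/spectra and numerical
failures.
"""


class PmmError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PmmError):
    """Invalid or inconsistent configuration (missing labels, bad thresholds...)."""


class ValidationError(PmmError):
    """Data violates a documented invariant."""


class ParseError(PmmError):
    """A file could not be parsed; the message names the offending record."""


class GeometryError(PmmError):
    """Degenerate geometry (collinear torsion points, charge on the expansion point)."""


class SelectionError(PmmError):
    """An atom/residue selection matched nothing."""


class FeasibilityError(PmmError):
    """A generator target cannot be met with the requested geometry."""


class NumericError(PmmError):
    """Numerical failure (eigensolver non-convergence and friends)."""


class DegenerateSpectrumError(PmmError):
    """A spectrum has fewer local maxima than a peak report needs.

    Carries the single peak found (if any) as ``.peak`` (wavelength nm, height).
    """

    def __init__(self, message: str, peak=None):
        super().__init__(message)
        self.peak = peak
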