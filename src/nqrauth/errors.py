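"""Exception hierarchy for nqrauth.

All errors derive from :class:`NQRAuthError` so callers (and the CLI) can
catch package failures with a single except clause while still reporting
a precise category.
"""


class NQRAuthError(Exception):
    """Base class for all nqrauth errors."""


class InvalidGeometryError(NQRAuthError, ValueError):
    """Coil or sample geometry is physically impossible."""


class DomainError(NQRAuthError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class InsufficientDataError(NQRAuthError, ValueError):
    """Too few data points for the requested fit or statistic."""


class FitFailureError(NQRAuthError, RuntimeError):
    """A model fit converged to a non-physical solution or did not converge."""


class IncompatibleDataError(NQRAuthError, ValueError):
    """Inputs that must share a configuration (time base, API, ...) do not."""


class NoPeakError(NQRAuthError, ValueError):
    """A spectrum is identically zero; no peak can be located."""


class GridError(NQRAuthError, ValueError):
    """A frequency sweep grid is non-uniform or too short."""


class InvalidSignatureError(NQRAuthError, ValueError):
    """A stored signature is unusable (e.g. zero spread)."""


class DegenerateSpreadError(InvalidSignatureError):
    """Feature spread is zero; a Gaussian signature cannot be formed."""


class FormatError(NQRAuthError, ValueError):
    """A file does not conform to the expected on-disk layout."""


class NumericalError(NQRAuthError, RuntimeError):
    """Quadrature or another numerical routine failed to converge."""
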