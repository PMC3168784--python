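"""Exception hierarchy for patlakp.

All package errors derive from :class:`PatlakPError` so callers can catch
one base class at pipeline boundaries.
"""


class PatlakPError(Exception):
    """Base class for all patlakp errors."""


class DomainError(PatlakPError):
    """Input outside the mathematical domain of an operation (e.g. negative time)."""


class OutOfRangeError(PatlakPError):
    """Requested evaluation point outside the support of a sampled curve."""


class UnsupportedError(PatlakPError):
    """Operation not defined for this input kind (e.g. infinite integral of samples)."""


class ConfigurationError(PatlakPError):
    """Inconsistent or incomplete configuration (missing labels, bad bounds...)."""


class InsufficientDataError(PatlakPError):
    """Too few frames / samples to perform a fit."""


class SingularNormalizationError(PatlakPError):
    """Normalizing denominator (e.g. AIF at a frame mid) is zero."""


class FitFailureError(PatlakPError):
    """All optimization starts failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class DegenerateTestError(PatlakPError):
    """Statistical test undefined for this input (zero-variance differences)."""


class FormatError(PatlakPError):
    """File contents do not match the expected on-disk format."""
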