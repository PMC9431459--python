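"""Package exception and warning types."""


class CrocoError(Exception):
    """Base class for package errors."""


class DomainError(CrocoError, ValueError):
    """An input is outside the mathematical domain of an operation."""


class ConfigurationError(CrocoError, ValueError):
    """Parameters or configuration are inconsistent with the requested operation."""


class InsufficientDataError(CrocoError, ValueError):
    """Too few observations to perform a fit."""


class DegenerateFitError(CrocoError, ValueError):
    """The design matrix of a fit is singular (e.g. a single bead diameter)."""


class IntegrationError(CrocoError, RuntimeError):
    """The ODE integrator produced a non-finite state."""


class AlignmentError(CrocoError, ValueError):
    """Two tables that must share an index do not align."""


class FitFailureError(CrocoError, RuntimeError):
    """Every optimizer start failed."""


class ExtrapolationWarning(UserWarning):
    """A forward-scatter value lies outside the bead calibration range."""
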