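"""Exception hierarchy for convdry.

All convdry-specific failures derive from :class:`ConvdryError` so callers
can catch the package's errors without masking programming mistakes.
"""


class ConvdryError(Exception):
    """Base class for all convdry errors."""


class InvalidInputError(ConvdryError, ValueError):
    """Input violates a documented precondition (shape, sign, ordering)."""


class DegenerateSeriesError(ConvdryError, ValueError):
    """A series is degenerate for the requested operation (e.g. M_0 == M_e,
    zero total variance, zero within-group variance everywhere)."""


class InsufficientDataError(ConvdryError, ValueError):
    """Too few usable observations for the requested estimate."""


class FitFailureError(ConvdryError, RuntimeError):
    """Nonlinear fit failed to converge from every starting point.

    Carries the best attempt (if any) in ``best_attempt``.
    """

    def __init__(self, message, best_attempt=None):
        super().__init__(message)
        self.best_attempt = best_attempt


class ConfigError(ConvdryError, ValueError):
    """Simulation or run configuration is inconsistent or non-physical."""
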