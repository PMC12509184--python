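"""Exception hierarchy for qsuppress.

All errors derive from :class:`QSuppressError` so callers can catch the
package's failures with a single except clause; the concrete subclasses
mirror the distinct failure modes of the pipeline (bad parameters,
infeasible pulse-timing corrections, degenerate profiles, fits that do
not converge).
"""


class QSuppressError(Exception):
    """Base class for all qsuppress errors."""


class InvalidParameterError(QSuppressError, ValueError):
    """A parameter violates its documented precondition."""


class InfeasibleCorrectionError(QSuppressError):
    """Time correction would require negative interpulse delays."""


class NoUsableRangeError(QSuppressError):
    """Profile lies entirely below the efficiency threshold."""


class InsufficientDataError(QSuppressError):
    """Too few data points for the requested statistic."""


class FitFailureError(QSuppressError):
    """Nonlinear fit failed to converge; carries diagnostics in args."""
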