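"""Exception hierarchy for oridir.

All analysis-level failures derive from :class:`OridirError` so callers can
catch one base class; each subclass names the condition that triggered it.
"""


class OridirError(Exception):
    """Base class for all oridir errors."""


class InvalidArgumentError(OridirError, ValueError):
    """A parameter is outside its documented domain (non-finite angle, bad flag)."""


class GridMismatchError(OridirError, ValueError):
    """A stimulus-angle grid lacks the structure an operation requires,
    e.g. a direction grid without opposite-direction partners."""


class InsufficientDataError(OridirError, ValueError):
    """Too few trials or cells for the requested statistic."""


class DegenerateDataError(OridirError, ValueError):
    """Data with no usable variation: singular covariance, zero-length
    mean vector, or an undefined orientation axis."""


class FitFailedError(OridirError, RuntimeError):
    """The constrained least-squares optimizer failed on every start.

    Carries ``diagnostics``, a list of per-start status messages.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []
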