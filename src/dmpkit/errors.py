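"""Exception hierarchy shared across the analysis stages.

Every stage raises a subclass of :class:`DmpkError`, so callers (the CLI,
the batch runners) can distinguish user-input problems from numerical
failures without string matching.
"""


class DmpkError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(DmpkError, ValueError):
    """A model or physiological parameter is outside its admissible range."""


class InvalidArgumentError(DmpkError, ValueError):
    """A call-level argument (empty list, unknown model name) is invalid."""


class InsufficientDataError(DmpkError, ValueError):
    """Too few observations for the requested operation."""


class DegenerateDataError(DmpkError, ValueError):
    """Data are structurally unusable (all-zero, non-positive where a log is needed)."""


class UnitMismatchError(DmpkError, ValueError):
    """Quantities on different bases (per-mg vs per-nmol) were combined."""


class NoDepletionError(DmpkError):
    """Substrate-depletion slope is non-negative; half-life is undefined.

    Carries the partial regression result in ``result`` when available.
    """

    def __init__(self, message: str, result=None):
        super().__init__(message)
        self.result = result


class NoEliminationError(DmpkError):
    """Terminal plasma slope is non-negative; elimination half-life is undefined."""


class FitFailureError(DmpkError):
    """Nonlinear fit did not converge; carries the best attempt in ``best``."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


class ConfigurationError(DmpkError):
    """A run configuration references missing files or out-of-range options."""
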