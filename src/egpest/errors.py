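"""Exception hierarchy for egpest."""


class EgpestError(Exception):
    """Base class for all egpest-specific errors."""


class InvalidInputError(EgpestError, ValueError):
    """Malformed or physically impossible input data."""


class DegenerateDesignError(EgpestError, ValueError):
    """Basal anchors (or drifts producing them) do not separate the meals,
    so the tracer-free problem has no unique ratio/A solution."""


class InfeasibleConfigError(EgpestError, ValueError):
    """A generator configuration implies negative basal levels."""


class EstimationFailedError(EgpestError, RuntimeError):
    """No multistart run converged; carries per-start diagnostics."""

    def __init__(self, message, starts=None):
        super().__init__(message)
        self.starts = starts


class InvalidNoiseError(EgpestError, ValueError):
    """Noise model produced a non-positive sigma at some sample."""


class UndefinedRSquaredError(EgpestError, ValueError):
    """R^2 requested for a constant observed series (zero total sum of squares)."""


class ParseError(EgpestError, ValueError):
    """CSV/config parsing failure; message names the offending row/column."""
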