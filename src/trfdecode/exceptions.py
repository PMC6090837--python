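"""Exception hierarchy shared across the toolbox."""


class TRFError(Exception):
    """Base class for all trfdecode errors."""


class InvalidInputError(TRFError, ValueError):
    """Input data violates a precondition (empty, non-finite, wrong length)."""


class InvalidParameterError(TRFError, ValueError):
    """A scalar parameter is outside its valid range."""


class ShapeError(TRFError, ValueError):
    """Array dimensions do not conform."""


class SingularMatrixError(TRFError, ValueError):
    """A matrix to be inverted is singular or ill-conditioned."""


class DegenerateInputError(TRFError, ValueError):
    """Input is degenerate for the requested operation (e.g. zero variance)."""


class FilterDesignError(TRFError, ValueError):
    """A digital filter design is unstable or infeasible."""


class TuningError(TRFError, RuntimeError):
    """Hyperparameter tuning could not select a value."""


class ConfigError(TRFError, ValueError):
    """Experiment configuration is invalid."""


class DataError(TRFError, ValueError):
    """Input files are missing or unreadable."""
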