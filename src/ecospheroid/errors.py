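"""Exception types shared across the package."""


class EcospheroidError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(EcospheroidError, ValueError):
    """A model parameter violates its domain (non-finite, wrong sign...)."""


class DivergenceError(EcospheroidError, RuntimeError):
    """Numerical integration blew up (e.g. strong mutualism).

    Carries ``last_valid_time``, the latest time at which the solution was
    still finite.
    """

    def __init__(self, message: str, last_valid_time: float | None = None):
        super().__init__(message)
        self.last_valid_time = last_valid_time


class EstimationError(EcospheroidError, RuntimeError):
    """A fit cannot be attempted (under-determined or degenerate data)."""


class SchemaError(EcospheroidError, ValueError):
    """An input table is missing required columns or malformed."""


class UndefinedResultError(EcospheroidError, RuntimeError):
    """A summary statistic is undefined for the given state."""
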