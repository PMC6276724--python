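"""Package-wide exception types."""


class ConfigurationError(ValueError):
    """Raised when generator or pipeline arguments are invalid."""


class InvalidInputError(ValueError):
    """Raised when supplied data violates an operation's preconditions."""


class ConvergenceError(RuntimeError):
    """Raised when an iterative solver fails to reach its tolerance."""

    def __init__(self, message: str, worst_violation: float | None = None):
        super().__init__(message)
        self.worst_violation = worst_violation
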