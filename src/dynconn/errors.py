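"""Exception hierarchy shared across the pipeline stages."""


class DynconnError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(DynconnError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(DynconnError, ValueError):
    """Input is syntactically valid but numerically degenerate
    (zero variance, zero mean centrality, empty margin, ...)."""


class FormatError(DynconnError, ValueError):
    """A file on disk does not match the expected layout; the message
    names the offending row/column where possible."""


class ConvergenceError(DynconnError, RuntimeError):
    """An iterative solver exhausted its iteration cap."""

    def __init__(self, message: str, last_objective: float | None = None):
        super().__init__(message)
        self.last_objective = last_objective
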