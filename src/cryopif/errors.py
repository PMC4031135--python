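"""Exception types shared across the package."""


class DomainError(ValueError):
    """An argument lies outside the physical domain of an operation."""


class IntegrationError(RuntimeError):
    """ODE integration failed; carries the last good state."""

    def __init__(self, message: str, last_T: float | None = None,
                 last_V: float | None = None):
        super().__init__(message)
        self.last_T = last_T
        self.last_V = last_V


class TableFormatError(ValueError):
    """A delimited-text table violates its schema; carries a line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class FitError(RuntimeError):
    """A fitting problem is degenerate (too few rates, single temperature, ...)."""
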