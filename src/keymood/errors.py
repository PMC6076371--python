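"""Exception hierarchy for keymood."""


class KeymoodError(Exception):
    """Base class for all keymood errors."""


class ParseError(KeymoodError):
    """A record in an on-disk log could not be parsed.

    Carries the 1-based line number of the offending record when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(KeymoodError):
    """A parsed record violates a domain invariant."""


class ConfigurationError(KeymoodError):
    """A configuration object violates its invariants."""


class ContractError(KeymoodError):
    """A caller violated a documented precondition."""


class FittingError(KeymoodError):
    """A model fit failed or did not converge."""


class UndefinedResultError(KeymoodError):
    """The requested statistic is undefined for the given input."""
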