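"""Exception types shared across the package."""


class TetralinkError(Exception):
    """Base class for package errors."""


class InvalidParameterError(TetralinkError, ValueError):
    """A simulation or analysis parameter is out of its valid range."""


class InvalidOperationError(TetralinkError, ValueError):
    """An operation was requested on an object in an incompatible state."""


class InsufficientDataError(TetralinkError, ValueError):
    """Too few informative observations to run an estimator."""


class NonParentalAlleleError(TetralinkError, ValueError):
    """A progeny call carries an allele absent from both parents."""


class ParseError(TetralinkError, ValueError):
    """A file did not conform to its documented dialect."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
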