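"""Exception hierarchy shared by all neurofuse modules."""


class NeurofuseError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(NeurofuseError, ValueError):
    """Invalid user-supplied parameter (bad interval, nonpositive count, ...)."""


class InputError(NeurofuseError, ValueError):
    """Structurally invalid input data (length mismatch, wrong dimension, ...)."""


class TrainingError(NeurofuseError, RuntimeError):
    """Model training failed (degenerate design, non-finite loss, ...)."""


class FilteringError(NeurofuseError, RuntimeError):
    """Kalman filtering failed (numerically singular innovation covariance)."""


class DecodingError(NeurofuseError, RuntimeError):
    """Decoding failed (rank-deficient decode system, model mismatch)."""


class TableFormatError(NeurofuseError, ValueError):
    """A delimited-text table could not be parsed; carries a line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConfigError(NeurofuseError, ValueError):
    """Invalid or unknown configuration keys/values."""
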