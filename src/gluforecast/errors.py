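"""Exception hierarchy shared across the package."""


class GluforecastError(Exception):
    """Base class for all package errors."""


class FormatError(GluforecastError):
    """Malformed input file (missing columns, unparseable fields)."""


class EmptyInputError(GluforecastError):
    """No usable rows / windows / samples."""


class DuplicateTimestampError(FormatError):
    """Two samples share the same instant."""


class ParameterError(GluforecastError, ValueError):
    """Invalid argument value or shape."""


class InsufficientDataError(GluforecastError):
    """Not enough samples for the requested statistic."""


class ConstantDataError(GluforecastError):
    """Zero-variance data where spread is required (e.g. scaler fit)."""


class DivergenceError(GluforecastError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite training loss at epoch {epoch}")


class ContractError(GluforecastError):
    """Caller violated a stated pre-condition (e.g. unscaled windows)."""


class SamplingError(GluforecastError):
    """Could not draw a feasible candidate from a constrained search space."""
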