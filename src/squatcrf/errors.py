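"""Exception hierarchy shared by all squatcrf modules."""


class SquatCRFError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SquatCRFError):
    """Raw recording file cannot be parsed (missing columns, bad cells, empty)."""


class InvalidMetadataError(SquatCRFError):
    """Recording metadata is inconsistent (e.g. non-positive sampling rate)."""


class PreconditionError(SquatCRFError):
    """An operation received input that violates its stated precondition."""


class ContractError(SquatCRFError):
    """An operation received arguments that violate its shape/length contract."""


class InsufficientDurationError(PreconditionError):
    """Recording is too short for the fixed analysis windows."""

    def __init__(self, required: int, actual: int):
        self.required = required
        self.actual = actual
        super().__init__(
            f"recording too short for segment extraction: "
            f"{actual} samples available, {required} required"
        )


class SchemaError(SquatCRFError):
    """Subject table is missing required columns."""


class SingularDesignError(SquatCRFError):
    """Regression design matrix is rank deficient."""


class UndefinedResultError(SquatCRFError):
    """A statistic is undefined for the given data (e.g. constant residuals)."""
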