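"""Exception hierarchy shared across the package."""


class CrossfeedError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(CrossfeedError, ValueError):
    """An argument violates a documented precondition."""


class CalibrationError(CrossfeedError):
    """A standard curve cannot be fitted or inverted."""


class EstimationError(CrossfeedError):
    """A statistic cannot be computed from the data provided."""


class QuantificationError(CrossfeedError):
    """A concentration cannot be derived from a measured response."""


class NumericalError(CrossfeedError):
    """An integrator or solver failed to meet its tolerance contract."""


class SchemaError(CrossfeedError):
    """A table or configuration file does not match its declared schema."""
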