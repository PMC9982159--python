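"""Exception hierarchy."""


class HeatmorbError(Exception):
    """Base class for all package errors."""


class SchemaError(HeatmorbError):
    """A file or frame does not satisfy the expected schema."""


class InvariantError(HeatmorbError):
    """A domain invariant was violated (e.g. total != indoor + outdoor)."""


class InsufficientHistoryError(HeatmorbError):
    """A lagged operator was asked for a day without enough preceding days."""


class SimulationInstabilityError(HeatmorbError):
    """The thermophysiological integration left its physical bounds."""

    def __init__(self, message: str, timestamp=None):
        super().__init__(message)
        self.timestamp = timestamp


class WeatherGapError(HeatmorbError):
    """The weather series has a gap too large to integrate across."""


class SingularDesignError(HeatmorbError):
    """A least-squares stage has an unidentifiable (degenerate) design."""
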