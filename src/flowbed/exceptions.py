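"""Exception hierarchy for flowbed."""


class FlowbedError(Exception):
    """Base class for all flowbed-specific errors."""


class ParseError(FlowbedError):
    """A text artifact (tracer log, spectra CSV, table) could not be parsed.

    Carries the 1-based line number of the offending line when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(FlowbedError, ValueError):
    """Well-formed input violating a domain invariant (monotonicity, bounds)."""


class SignalQualityError(FlowbedError):
    """A tracer signal is unusable, e.g. the step is buried in noise."""


class DataInconsistencyError(FlowbedError):
    """Physically impossible combination of measurements, e.g. an outlet
    residence-time moment smaller than the inlet one."""


class CampaignError(FlowbedError):
    """An optimization campaign could not be completed."""
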