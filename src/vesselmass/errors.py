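"""Exception hierarchy for vesselmass."""


class VesselMassError(Exception):
    """Base class for all vesselmass errors."""


class ConfigurationError(VesselMassError):
    """A configuration (column mapping, strategy file, fleet config) is invalid."""


class RecordValidationError(VesselMassError):
    """One or more vessel records failed validation.

    Carries the per-record messages so callers can report them instead of
    silently dropping rows.
    """

    def __init__(self, messages: list[str]):
        self.messages = list(messages)
        super().__init__(
            f"{len(self.messages)} invalid record(s): " + "; ".join(self.messages)
        )


class EstimationError(VesselMassError):
    """A record has no usable mass field for displacement estimation."""


class FittingError(VesselMassError):
    """The regression cannot be fitted on the provided data."""


class ContrastError(VesselMassError):
    """Pairwise type contrasts require at least two vessel types."""


class DataIntegrityError(VesselMassError):
    """A packaged coefficient file failed its schema or consistency checks."""


class LookupError_(VesselMassError):
    """An unknown vessel type was requested from a coefficient set."""


class ContractViolationError(VesselMassError):
    """A plug-in lethality model returned a probability outside [0, 1]."""
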