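"""Exception hierarchy for the pipeline."""


class ThreatDynError(Exception):
    """Base class for all package errors."""


class SchemaError(ThreatDynError):
    """A file does not conform to one of the declared schemas."""


class ValidationError(ThreatDynError):
    """A record violates a domain invariant."""


class JoinError(ThreatDynError):
    """Tables cannot be joined because records are missing."""


class DegenerateTrajectoryError(ThreatDynError):
    """Trajectory start and end coincide; no chord to normalize against."""


class SeriesTooShortError(ThreatDynError):
    """Series is too short for the requested embedding."""


class EntropyUndefinedError(ThreatDynError):
    """Every cell of the entropy grid was undefined."""


class ConvergenceError(ThreatDynError):
    """Sampler diagnostics exceeded tolerance.

    Carries ``parameters``: the names of the offending parameters.
    """

    def __init__(self, message, parameters=()):
        super().__init__(message)
        self.parameters = tuple(parameters)


class ConfigError(ThreatDynError):
    """Pipeline configuration is invalid."""
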