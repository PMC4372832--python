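"""Exception hierarchy for the defol package."""


class DefolError(Exception):
    """Base class for all defol errors."""


class SchemaError(DefolError):
    """A delimited-text file is missing a required column or is malformed."""


class ValidationError(DefolError):
    """A row violates a domain-type invariant.

    Carries the offending identifier and a human-readable reason so that
    bad rows can be reported precisely.
    """

    def __init__(self, message: str, plant_id: str | None = None):
        super().__init__(message)
        self.plant_id = plant_id


class FitError(DefolError):
    """A smoothing fit is infeasible (too few distinct times, empty data)."""


class DomainError(DefolError):
    """A value lies outside the mathematically valid domain of an operation."""


class StageError(DefolError):
    """Stage classification is impossible (e.g. no detectable shock)."""
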