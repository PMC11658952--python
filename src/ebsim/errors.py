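"""Exception hierarchy.

Everything raised deliberately by this package derives from :class:`EbsimError`
so callers (and the CLI) can distinguish user-facing input problems from
internal failures.
"""


class EbsimError(Exception):
    """Base class for all errors raised by ebsim."""


class InvalidInputError(EbsimError, ValueError):
    """A scalar argument or domain object violates its precondition."""


class SimulationDivergedError(EbsimError, RuntimeError):
    """The integrated weight left the physically meaningful domain.

    Carries the day at which the failure was detected in ``.day`` when known.
    """

    def __init__(self, message: str, day: float | None = None):
        super().__init__(message)
        self.day = day


class ConfigError(EbsimError):
    """A configuration file or mapping is malformed (unknown/missing keys)."""


class SchemaError(EbsimError):
    """A tabular input lacks required columns."""


class CsvParseError(EbsimError):
    """A cell in a CSV input could not be parsed; names the offending line."""


class InvalidSpecError(EbsimError):
    """A synthetic-cohort specification is infeasible."""
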