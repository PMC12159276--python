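"""Exception hierarchy for pvsignals."""


class PvSignalsError(Exception):
    """Base class for all pvsignals errors."""


class DialectError(PvSignalsError):
    """A delimited input file does not conform to the declared dialect
    (e.g. a mandatory column is missing)."""


class ValidationError(PvSignalsError):
    """A domain object violates one of its invariants."""


class UndefinedEstimateError(PvSignalsError):
    """A disproportionality estimate is undefined for the given table
    (zero cell without continuity correction)."""


class InfeasibleMarginsError(ValidationError):
    """A margin specification cannot be realised by any report set."""
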