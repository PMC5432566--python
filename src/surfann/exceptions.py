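"""Exception hierarchy for surfann."""


class SurfannError(Exception):
    """Base class for all surfann errors."""


class UnknownResidueError(SurfannError, KeyError):
    """A residue symbol is not present in the mass table."""

    def __init__(self, symbol: str):
        super().__init__(symbol)
        self.symbol = symbol

    def __str__(self) -> str:  # KeyError quotes its arg; keep a readable message
        return f"unknown residue symbol: {self.symbol!r}"


class DomainError(SurfannError, ValueError):
    """An argument lies outside the mathematically valid domain."""


class ParseError(SurfannError, ValueError):
    """A peak-list file is malformed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class SchemaError(SurfannError, ValueError):
    """A delimited table is missing a mandated column or field."""


class InconsistencyError(SurfannError, ValueError):
    """A mass-balance computation produced an impossible (e.g. negative) value."""


class GenerationError(SurfannError, RuntimeError):
    """The synthetic-data generator could not satisfy its constraints."""


class AlignmentError(SurfannError, ValueError):
    """Bioassay rows could not be matched to a time-aligned control."""

    def __init__(self, message: str, orphans=None):
        super().__init__(message)
        self.orphans = list(orphans or [])


class QualityControlError(SurfannError, ValueError):
    """A bioassay control (positive/negative) failed; names the control."""

    def __init__(self, control: str, message: str):
        super().__init__(message)
        self.control = control
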