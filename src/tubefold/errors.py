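"""Exception hierarchy."""


class TubefoldError(Exception):
    """Base class for all tubefold errors."""


class StructureParseError(TubefoldError, ValueError):
    """Raised when a structure notation string cannot be parsed.

    Carries the 0-based position in the input text where parsing failed.
    """

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class SequenceError(TubefoldError, ValueError):
    """Illegal sequence text or nucleotide letter."""


class ModelError(TubefoldError):
    """Physical-model violation: invalid pair, unsupported material pair,
    missing parameter context, pseudoknotted input to the loop model."""


class ParameterError(TubefoldError, ValueError):
    """Malformed or incomplete free-energy parameter file."""


class EnsembleCapError(TubefoldError):
    """Total complex length exceeds the configured enumeration cap."""


class ConvergenceError(TubefoldError):
    """The equilibrium-concentration solver failed to reach tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        self.residual = residual
        super().__init__(message)


class ConstraintError(TubefoldError, ValueError):
    """Ill-formed or infeasible design constraint system."""


class ConfigError(TubefoldError, ValueError):
    """Invalid job configuration (bad ranges, unknown fields)."""
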