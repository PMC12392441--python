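"""Exception hierarchy shared across the package."""


class PegScissionError(Exception):
    """Base class for all package-specific errors."""


class DomainError(PegScissionError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ValidationError(PegScissionError, ValueError):
    """A structured input (grid, table, config) fails its contract."""


class UnreachableExtentError(DomainError):
    """A requested scission extent exceeds what full conversion allows."""


class ExhaustedEnsembleError(PegScissionError, RuntimeError):
    """No chain of length >= 2 remains, so no further scission is possible."""

    def __init__(self, message: str, achieved_sic: float | None = None):
        super().__init__(message)
        self.achieved_sic = achieved_sic


class GenealogyIntegrityError(PegScissionError, RuntimeError):
    """A genealogy record violates its bookkeeping identities."""


class FitDegenerateError(PegScissionError, ValueError):
    """The experimental curve carries no information about the fit."""
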