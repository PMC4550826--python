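"""Exception hierarchy for summary-statistic MR analyses."""


class TelomrError(Exception):
    """Base class for all package errors."""


class SummaryFormatError(TelomrError):
    """A summary-statistic table could not be parsed (e.g. missing column)."""


class DomainError(TelomrError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class AlleleMismatchError(TelomrError):
    """Neither outcome allele matches the instrument's long-TL allele."""


class PalindromicAlleleError(TelomrError):
    """A/T or C/G allele pair: orientation is ambiguous without strand info."""


class EmptyInstrumentError(TelomrError):
    """An operation that needs at least one instrument received none."""


class DegreesOfFreedomError(TelomrError):
    """Too few instruments for the requested test (K - 1 df requires K >= 2)."""


class ConvergenceError(TelomrError):
    """Likelihood optimisation failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
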