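"""Exception hierarchy shared across the package."""


class DielFluxError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DielFluxError):
    """A file or serialized record does not match the expected layout."""


class ValidationError(DielFluxError):
    """Input data violates a stated invariant (e.g. negative FPKM)."""


class ConfigError(DielFluxError):
    """An option set or specification object is internally inconsistent."""


class GPRParseError(DielFluxError):
    """A gene-protein-reaction rule string could not be parsed.

    Carries the character position of the offending token when known.
    """

    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)
        self.position = position


class CalibrationError(DielFluxError):
    """The flux-ceiling calibration against light availability failed."""


class UnfittableGeneError(DielFluxError):
    """No candidate expression family produced a finite AICc for a gene."""
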