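"""Exception hierarchy.

``ValidationError`` covers malformed inputs and violated invariants (CLI exit
code 2); ``NumericalError`` covers failures of the numerical machinery itself
(CLI exit code 3).
"""


class ITCKineticsError(Exception):
    """Base class for all package errors."""


class ValidationError(ITCKineticsError, ValueError):
    """Invalid input data, configuration, or violated type invariant."""


class ParseError(ValidationError):
    """A delimited-text input file could not be parsed."""


class IncompleteConversionError(ValidationError):
    """Power did not return to baseline before the next injection, so the
    per-injection heat cannot be attributed to complete substrate turnover."""


class NumericalError(ITCKineticsError, RuntimeError):
    """An integrator or optimizer failed."""


class StageError(ITCKineticsError):
    """A pipeline stage failed; carries the stage name and a remediation hint."""

    def __init__(self, stage: str, message: str, hint: str = ""):
        self.stage = stage
        self.hint = hint
        text = f"[stage: {stage}] {message}"
        if hint:
            text += f" (hint: {hint})"
        super().__init__(text)
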