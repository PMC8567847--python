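"""Exception hierarchy for the baleendo package."""


class BaleendoError(Exception):
    """Base class for all package errors."""


class FormatError(BaleendoError):
    """A table or file does not have the expected structure."""


class ParseError(BaleendoError):
    """A cell could not be parsed; carries the offending row index."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class ScenarioError(BaleendoError):
    """A simulation scenario is internally inconsistent."""


class AssayQCError(BaleendoError):
    """An immunoassay quality-control precondition failed."""


class CurveFitError(BaleendoError):
    """The standard curve could not be fitted."""


class ExtrapolationError(BaleendoError):
    """A concentration falls outside the validated standard-curve range."""


class ChronologyError(BaleendoError):
    """The isotope chronology could not be built."""


class InsufficientPeaksError(ChronologyError):
    """Fewer than two isotope peaks: no cycle-wise growth rate available."""


class FitError(BaleendoError):
    """A statistical model fit failed or is degenerate."""


class PipelineError(BaleendoError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original
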