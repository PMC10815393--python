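"""Exception hierarchy for cftrfreq."""


class CftrFreqError(Exception):
    """Base class for all package-specific errors."""


class ParseError(CftrFreqError, ValueError):
    """A table cell could not be interpreted (names the row and column)."""


class ValidationError(CftrFreqError, ValueError):
    """A domain object violates one of its invariants."""


class MissingDataError(CftrFreqError, ValueError):
    """An operation required a value that is MISSING (never coerced to 0)."""


class DegenerateTableError(CftrFreqError, ValueError):
    """A contingency table has a zero margin and no test statistic exists."""


class PipelineError(CftrFreqError, RuntimeError):
    """A pipeline stage failed; carries the stage name and offending record."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
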