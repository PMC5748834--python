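"""Exception hierarchy shared across the package."""


class QsarError(Exception):
    """Base class for all qsarize errors."""


class ParseError(QsarError, ValueError):
    """A structure or activity record could not be parsed.

    ``record_index`` is the 1-based position of the offending record in its
    source file (SDF block or CSV data row), when known.
    """

    def __init__(self, message: str, record_index: int | None = None):
        super().__init__(message)
        self.record_index = record_index


class AlignmentError(QsarError, ValueError):
    """Molecule and activity lists cannot be aligned positionally."""


class PipelineStageError(QsarError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
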