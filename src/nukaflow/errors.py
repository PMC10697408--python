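"""Exception hierarchy shared across the pipeline."""


class NukaflowError(Exception):
    """Base class for all pipeline errors."""


class FormatError(NukaflowError):
    """Malformed input file (bad header, non-integer counts, duplicates...)."""


class VocabularyError(NukaflowError):
    """A controlled-vocabulary field carries an unknown value."""


class UniquenessError(NukaflowError):
    """A key that must be unique appears more than once."""


class AlignmentError(NukaflowError):
    """Table / metadata / taxonomy identifiers cannot be reconciled."""


class ValidationError(NukaflowError):
    """A configuration or parameter value is out of range or unknown."""


class PipelineError(NukaflowError):
    """A pipeline stage failed; carries the stage name for the log."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
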