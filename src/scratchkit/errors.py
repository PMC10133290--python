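"""Typed exceptions raised across the pipeline."""


class ScratchkitError(Exception):
    """Base class for all package errors."""


class SchemaError(ScratchkitError):
    """A file does not match the expected column schema."""


class VocabularyError(SchemaError):
    """An annotation label is outside the fixed event vocabulary."""


class RateMismatchError(ScratchkitError):
    """Declared sampling rate disagrees with the observed inter-sample gap."""


class AlignmentError(ScratchkitError):
    """Annotation-to-sensor time alignment cannot be estimated."""


class OverlapError(ScratchkitError):
    """Events overlap on the same hand."""


class StageError(ScratchkitError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
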