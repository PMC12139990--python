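"""Exception types shared across the pipeline."""


class DrugsigError(Exception):
    """Base class for all package errors."""


class FormatError(DrugsigError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(DrugsigError):
    """Parsed content violates a domain invariant (range, uniqueness, resolution)."""


class StageError(DrugsigError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
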