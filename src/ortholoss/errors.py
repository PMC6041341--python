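"""Exception types shared across the package."""


class OrtholossError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(OrtholossError, ValueError):
    """An input file could not be parsed; the message names the offending line."""


class ValidationError(OrtholossError, ValueError):
    """An argument or data structure violates a documented precondition."""


class StageError(OrtholossError, RuntimeError):
    """A pipeline stage failed; carries the stage name for exit-code mapping."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
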