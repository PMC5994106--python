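"""Exception hierarchy for the sevscan pipeline."""


class SevscanError(Exception):
    """Base class for all sevscan errors."""


class ConfigError(SevscanError):
    """Invalid simulation or run configuration."""


class ParseError(SevscanError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class ValidationError(SevscanError):
    """Input data violates a documented contract."""


class StageError(SevscanError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
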