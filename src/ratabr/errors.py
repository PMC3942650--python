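"""Exception hierarchy.

Three failure classes are distinguished so callers (and the CLI) can map them
to exit codes: bad user data (:class:`InputError`), bad settings
(:class:`ConfigurationError`), and simulation dead-ends
(:class:`GenerationError`).
"""


class RatabrError(Exception):
    """Base class for all package errors."""


class InputError(RatabrError):
    """Malformed or inconsistent input data (traces, images, tables)."""


class ConfigurationError(RatabrError):
    """Invalid parameter or design settings."""


class GenerationError(RatabrError):
    """A synthetic dataset could not be realised (e.g. geometry not placeable)."""


class PipelineError(RatabrError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
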