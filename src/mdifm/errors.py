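"""Structured exceptions raised across the pipeline stages."""


class MdifmError(Exception):
    """Base class for all package-specific errors."""


class WaterPerceptionError(MdifmError):
    """A frame could not be decomposed into intact water molecules.

    Carries the offending atom index so callers can report which atom
    broke the O/2H bookkeeping.
    """

    def __init__(self, message: str, atom_index: int | None = None):
        super().__init__(message)
        self.atom_index = atom_index


class ShellStructureError(MdifmError):
    """The radial distribution function shows no usable shell structure."""


class EngineError(MdifmError):
    """An external frequency engine failed; diagnostics are attached."""

    def __init__(self, message: str, diagnostics: str = ""):
        super().__init__(message)
        self.diagnostics = diagnostics


class ModeAssignmentError(MdifmError):
    """A mode window contained no candidate frequency for a snapshot."""

    def __init__(self, message: str, window: str = "", snapshot=None):
        super().__init__(message)
        self.window = window
        self.snapshot = snapshot


class FitConvergenceError(MdifmError):
    """All fit starts failed to converge."""


class ConfigError(MdifmError):
    """A run configuration is invalid or references missing files."""
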