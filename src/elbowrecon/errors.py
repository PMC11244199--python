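"""Exception hierarchy.

Exit-code mapping used by the CLI: usage errors -> 2 (typer), DataError -> 3,
AnatomicalAssumptionError -> 4.
"""


class ElbowreconError(Exception):
    """Base class for all package errors."""


class DataError(ElbowreconError):
    """Malformed or unsupported input data (files, shapes, metadata)."""


class AnatomicalAssumptionError(ElbowreconError):
    """A scene violates an anatomical assumption the method relies on."""


class AmbiguousSceneError(AnatomicalAssumptionError):
    """A decision rule (argmax / projection) is tied within tolerance."""


class StageError(ElbowreconError):
    """Failure inside a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
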