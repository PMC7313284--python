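"""Exception types raised across the package."""


class ActiseqError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ActiseqError, ValueError):
    """A file on disk does not match the expected layout (ragged rows,
    non-numeric cells, empty file)."""


class ConvergenceError(ActiseqError, RuntimeError):
    """The SMO solver hit its iteration cap before reaching the KKT
    tolerance.  Carries the remaining duality gap for diagnosis."""

    def __init__(self, message: str, gap: float):
        super().__init__(f"{message} (duality gap {gap:.3e})")
        self.gap = gap
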