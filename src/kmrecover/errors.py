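"""Exception hierarchy.

All recoverable tool failures derive from :class:`RecoverError` so the CLI can
map them to a data/validation exit status distinct from usage errors.
"""


class RecoverError(Exception):
    """Base class for data / validation failures."""


class PostScriptError(RecoverError):
    """Input is not parseable PostScript text, or the path structure is invalid."""

    def __init__(self, message: str, offset: int | None = None, token_index: int | None = None):
        self.offset = offset
        self.token_index = token_index
        parts = [message]
        if offset is not None:
            parts.append(f"(byte offset {offset})")
        if token_index is not None:
            parts.append(f"(token index {token_index})")
        super().__init__(" ".join(parts))


class CalibrationError(RecoverError):
    """Degenerate or inconsistent axis anchors."""


class StepFunctionError(RecoverError):
    """Segments do not form a step function within tolerance."""


class ReconstructionError(RecoverError):
    """Curve inversion produced an inconsistent risk-set table."""
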