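"""Exception hierarchy shared by the pipeline modules."""


class DosecmapError(Exception):
    """Base class for all package errors."""


class ParameterError(DosecmapError, ValueError):
    """A user-supplied parameter violates a precondition."""


class ContractViolation(DosecmapError, ValueError):
    """An input object violates a documented invariant (e.g. overlapping
    up/down halves of a directional set)."""


class EmptySignatureError(DosecmapError, ValueError):
    """A signature operation produced a query with no usable genes."""


class FormatError(DosecmapError, ValueError):
    """A file failed to parse; carries file and line context where known."""

    def __init__(self, message: str, path: str | None = None,
                 line: int | None = None):
        ctx = ""
        if path is not None:
            ctx = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + ctx)
        self.path = path
        self.line = line
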