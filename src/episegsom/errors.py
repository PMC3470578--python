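"""Exception hierarchy shared across the package."""


class EpisegsomError(Exception):
    """Base class for all package-specific errors."""


class ParseError(EpisegsomError):
    """A file could not be parsed; carries the offending line number when known."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class BoundsError(EpisegsomError):
    """A coordinate falls outside the genome layout."""


class ValidationError(EpisegsomError):
    """An input violates a documented invariant."""
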