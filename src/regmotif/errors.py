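"""Exception types shared across the package."""


class RegmotifError(Exception):
    """Base class for all package-specific errors."""


class NetworkParseError(RegmotifError):
    """A network file could not be parsed.

    Carries the offending path and 1-based line number when known.
    """

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class ValidationError(RegmotifError):
    """An object violates a structural invariant."""


class AnalysisError(RegmotifError):
    """A numerical analysis could not produce a reliable answer."""


class CapacityError(RegmotifError):
    """A generator request cannot be satisfied within its retry budget."""
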