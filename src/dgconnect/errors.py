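"""Exception hierarchy.

ValidationError covers bad user input (CLI maps it to exit code 2);
ParseError adds a file location. Everything else is a runtime failure.
"""


class DGConnectError(Exception):
    """Base class for all package errors."""


class ValidationError(DGConnectError):
    """Invalid input values or usage (CLI exit code 2)."""


class ParseError(ValidationError):
    """Malformed input file; carries the offending line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}:"
        if line is not None:
            loc += f"{line}: "
        elif loc:
            loc += " "
        super().__init__(f"{loc}{message}")
        self.path = path
        self.line = line
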