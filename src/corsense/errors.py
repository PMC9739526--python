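"""Exception hierarchy.

``ValidationError`` marks bad user input (CLI maps it to exit code 2);
``FormatError`` marks a malformed file and carries the offending line number.
"""


class CorsenseError(Exception):
    """Base class for all package errors."""


class ValidationError(CorsenseError, ValueError):
    """Invalid parameter or precondition violation."""


class FormatError(CorsenseError, ValueError):
    """Malformed input file."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc = f" [{loc}]"
        super().__init__(f"{message}{loc}")
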