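"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ConfigError -> 2, ParseError and
ValidationError -> 3, any other NipevoError -> 4.
"""


class NipevoError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(NipevoError):
    """Invalid or incomplete run configuration."""


class ParseError(NipevoError):
    """Malformed input file; carries file name and line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class ValidationError(NipevoError):
    """Input parsed but violates a domain invariant."""
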