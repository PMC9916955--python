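"""Exception hierarchy shared across the package.

Three broad failure classes map onto the pipeline's exit codes:
configuration problems (bad arena/protocol/config values), data problems
(malformed or invariant-violating input), and parse problems (a special
case of data problems that can name the offending line).
"""


class SwimmetricsError(Exception):
    """Base class for all package errors."""


class ConfigError(SwimmetricsError):
    """Invalid configuration: arena/protocol/preset/pipeline parameters."""


class DataError(SwimmetricsError):
    """Input data violates an invariant (non-monotone time, point outside arena...)."""


class ParseError(DataError):
    """Malformed input file; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
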