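"""Exception hierarchy.

Invalid *data* is never an error anywhere in the pipeline — it is flagged and
reported. Exceptions are reserved for misconfiguration and I/O problems.
"""


class SumstatFixError(Exception):
    """Base class for all package errors."""


class ConfigError(SumstatFixError):
    """Malformed or inconsistent column-mapping configuration."""


class PlanningError(SumstatFixError):
    """Restoration cannot be planned with the resources provided."""


class ChainParseError(SumstatFixError):
    """Malformed UCSC chain file."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class PreprocessError(SumstatFixError):
    """dbSNP preprocessing produced no usable records."""


class EvaluationError(SumstatFixError):
    """Original and restored tables cannot be compared."""


class ParameterError(SumstatFixError, ValueError):
    """A function parameter is out of its documented domain."""
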