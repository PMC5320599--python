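"""Exception hierarchy shared across the pipeline.

Validation problems (bad inputs, contract violations) raise
:class:`ValidationError`; infeasible simulation configurations raise
:class:`ConfigError`.  The CLI maps ValidationError to exit code 1 and any
other failure to exit code 2.
"""


class ValidationError(ValueError):
    """Input data violates a documented precondition."""


class ConfigError(ValidationError):
    """A simulation or run configuration is infeasible or inconsistent."""


class GFFParseError(ValidationError):
    """A GFF3 stream could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"GFF3 parse error at line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class PipelineError(RuntimeError):
    """A pipeline stage failed; wraps the underlying error with stage context."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original
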