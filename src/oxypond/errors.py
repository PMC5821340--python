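"""Exception hierarchy for oxypond.

Every error raised on a user-facing path derives from :class:`OxypondError`
so the CLI can map library failures to a single nonzero exit code while
usage errors stay with click's exit 2.
"""


class OxypondError(Exception):
    """Base class for all oxypond errors."""


class SchemaError(OxypondError):
    """A required column is missing or the header does not match the schema."""


class ParseError(OxypondError):
    """A cell could not be converted to the expected type."""


class EmptyInputError(OxypondError):
    """The file contains a header but no data rows."""


class ValidationError(OxypondError):
    """A parsed record violates a domain invariant (e.g. humidity > 100)."""


class CalibrationError(OxypondError):
    """No neighbourhood radius reproduces the requested cluster count."""


class DegenerateCentersError(OxypondError):
    """Fewer than two distinct centers: the shared RBF width is undefined."""


class ConditioningError(OxypondError):
    """The least-squares solve returned non-finite weights."""


class StageError(OxypondError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"[stage: {stage}] {cause}")
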