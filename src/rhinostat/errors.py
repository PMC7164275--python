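"""Exception hierarchy.

Every error raised on user input carries a short machine-readable ``code``
so the CLI and file readers can report validated failures uniformly.
"""


class RhinostatError(Exception):
    """Base class for all package errors."""

    code = "error"

    def __init__(self, message: str, **context):
        super().__init__(message)
        self.context = context


class DesignError(RhinostatError):
    """Study design too small for the requested analysis (n < 2 or k < 2)."""

    code = "design"


class MissingDataError(RhinostatError):
    """Missing entries in a repeated-measures table; callers must pre-filter."""

    code = "missing_data"


class PositivityError(RhinostatError):
    """A coefficient of variation was requested for data with mean <= 0."""

    code = "positivity"


class AgreementUndefinedError(RhinostatError):
    """All values identical: both variance components are zero and the ICC
    is 0/0."""

    code = "agreement_undefined"


class InfeasibleDesignError(RhinostatError):
    """Sample-size request that no finite n can satisfy."""

    code = "infeasible_design"


class ConfigError(RhinostatError):
    """Invalid simulation / generator / run configuration."""

    code = "config"


class SchemaError(RhinostatError):
    """Input file does not match the long-format dialect."""

    code = "schema"


class DuplicateKeyError(SchemaError):
    code = "duplicate_key"


class ValueParseError(SchemaError):
    code = "nonnumeric_value"
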