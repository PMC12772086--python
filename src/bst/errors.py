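"""Exception hierarchy shared across the package."""


class BstError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(BstError):
    """An invalid configuration value; carries the offending field name."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field '{field}': {message}")


class SchemaError(BstError):
    """A table does not match the expected schema."""

    def __init__(self, message: str, missing=(), extra=()):
        self.missing = list(missing)
        self.extra = list(extra)
        detail = message
        if self.missing:
            detail += f"; missing columns: {self.missing}"
        if self.extra:
            detail += f"; unexpected columns: {self.extra}"
        super().__init__(detail)


class LikertParseError(BstError):
    """An answer label that is not legal for the item's response scale."""

    def __init__(self, label, item_id=None, row=None):
        self.label = label
        self.item_id = item_id
        self.row = row
        where = ""
        if item_id is not None:
            where += f" for item '{item_id}'"
        if row is not None:
            where += f" at row {row}"
        super().__init__(f"unrecognised Likert label {label!r}{where}")


class RecodeError(BstError):
    """A value outside the legal range of an ordinal recoding."""


class AliasingError(BstError):
    """Design matrix is rank deficient; lists the aliased columns."""

    def __init__(self, aliased_columns):
        self.aliased_columns = list(aliased_columns)
        super().__init__(
            "design matrix is rank deficient; aliased columns: "
            + ", ".join(map(str, self.aliased_columns))
        )


class ConvergenceError(BstError):
    """An iterative fit failed to converge within the iteration budget."""


class PipelineError(BstError):
    """A pipeline stage failed; carries the stage name and a machine-readable record."""

    def __init__(self, stage: str, message: str, cause: Exception | None = None):
        self.stage = stage
        self.cause = cause
        self.record = {
            "stage": stage,
            "error": message,
            "cause_type": type(cause).__name__ if cause is not None else None,
        }
        super().__init__(f"pipeline stage '{stage}' failed: {message}")
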