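"""Exception hierarchy for the plastrend pipeline.

Every stage raises subclasses of :class:`PlastrendError` so the pipeline
driver can attach stage context while letting callers catch one base type.
"""


class PlastrendError(Exception):
    """Base class for all plastrend errors."""


class InvalidGeometryError(PlastrendError):
    """Tow geometry (width/distance) is non-positive or otherwise unusable."""


class MissingGeometryError(PlastrendError):
    """Neither a swept area nor a (width, distance) pair is resolvable."""


class SchemaError(PlastrendError):
    """A required column is missing from a station table."""

    def __init__(self, missing_columns):
        self.missing_columns = list(missing_columns)
        super().__init__(
            "missing mandatory column(s): " + ", ".join(self.missing_columns)
        )


class ValidationError(PlastrendError):
    """One or more rows of a station table failed validation.

    ``row_errors`` is a list of ``(line_number, message)`` pairs where the
    line number refers to the physical line in the source CSV (header = 1).
    """

    def __init__(self, row_errors):
        self.row_errors = list(row_errors)
        lines = "; ".join(f"line {ln}: {msg}" for ln, msg in self.row_errors[:10])
        extra = "" if len(self.row_errors) <= 10 else f" (+{len(self.row_errors) - 10} more)"
        super().__init__(f"{len(self.row_errors)} malformed row(s): {lines}{extra}")


class InvalidDateError(PlastrendError):
    """Month outside 1..12 or otherwise unparseable date."""


class BasinAssignmentError(PlastrendError):
    """A station could not be assigned to any ocean basin."""


class DegenerateBasinError(PlastrendError):
    """A basin has too few cells (or zero variance) to be z-scored."""


class FieldStateError(PlastrendError):
    """Expected-concentration field is in the wrong scaled/unscaled state."""


class FieldLookupError(PlastrendError):
    """No ocean cell within the search radius of a query point."""


class InsufficientDataError(PlastrendError):
    """Too few uncensored values (or too high a censored fraction) to impute."""


class ModelError(PlastrendError):
    """A model fit failed (singular design, impossible preconditions...)."""


class ConfigError(PlastrendError):
    """A simulation or pipeline configuration violates its invariants."""


class StageError(PlastrendError):
    """Wraps any stage failure with the stage name for pipeline reporting."""

    def __init__(self, stage, original):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original}")
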