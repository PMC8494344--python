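"""Exception hierarchy for the field-sampling workflow.

Anomalies found in field data are flagged, never raised; exceptions are
reserved for conditions that make a project unreadable or a result
meaningless (missing exports, broken schemas, referential-integrity
violations).
"""


class FulcrumError(Exception):
    """Base class for all workflow errors."""


class InvalidPathError(FulcrumError):
    """Project root exists but is not a usable directory."""


class MissingExportError(FulcrumError):
    """No CSV export following the ``<prefix>_field_sampling.csv`` convention."""


class AmbiguousPrefixError(FulcrumError):
    """Two or more distinct export prefixes in the raw directory."""

    def __init__(self, prefixes):
        self.prefixes = sorted(prefixes)
        super().__init__(
            "multiple export prefixes found: " + ", ".join(self.prefixes)
        )


class SchemaError(FulcrumError):
    """A required column is absent, or a header is malformed."""


class ParseError(FulcrumError):
    """A CSV row or cell could not be parsed."""


class IntegrityError(FulcrumError):
    """Referential-integrity violation (e.g. duplicate record identifiers)."""


class LookupError_(FulcrumError):
    """A record/field pair named in a repair request does not exist."""


class InvalidFeatureError(FulcrumError):
    """A geographic feature is degenerate or lacks required properties."""


class OrderingError(FulcrumError):
    """A workflow stage was invoked before its prerequisite stage."""

    def __init__(self, stage: str, missing_stage: str):
        self.stage = stage
        self.missing_stage = missing_stage
        super().__init__(
            f"stage '{stage}' requires output of stage '{missing_stage}', "
            f"which has not been run"
        )


class EmptyStatsError(FulcrumError):
    """Summary statistics requested for an all-missing series."""


class FixtureSpecError(FulcrumError):
    """A synthetic-fixture specification is out of range."""
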