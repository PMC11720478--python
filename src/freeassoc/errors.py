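"""Exception hierarchy for the free-association analysis pipeline."""


class FreeAssocError(Exception):
    """Base class for all package errors."""


class SchemaError(FreeAssocError):
    """Input table does not have the required columns or column types."""


class IntegrityError(FreeAssocError):
    """Referential or covariate integrity is violated (e.g. one participant
    carries conflicting covariate values)."""


class StateError(FreeAssocError):
    """Operation called in the wrong pipeline state (e.g. normalizing after
    targets were set, clustering before embedding)."""


class UsageError(FreeAssocError, ValueError):
    """Invalid argument value (unknown keyword, out-of-range parameter)."""


class ProcessingError(FreeAssocError):
    """A user-supplied transform failed or returned a non-string."""


class ConfigurationError(FreeAssocError):
    """Invalid generator or pipeline configuration."""
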