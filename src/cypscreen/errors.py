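"""Exception hierarchy shared across the pipeline."""


class CypscreenError(Exception):
    """Base class for all package errors."""


class SchemaError(CypscreenError):
    """A delimited input file lacks required columns or has a bad layout."""


class EmptyInputError(CypscreenError):
    """An operation received no usable records."""


class LabelConflictError(CypscreenError):
    """Both labeling rules fired for the same compound."""


class ParseError(CypscreenError):
    """Free-text input (e.g. a docking log) could not be parsed."""


class IncompleteProfileError(CypscreenError):
    """An interaction-energy profile is missing conformations where
    completeness is required."""


class BundleError(CypscreenError):
    """A model bundle is missing, corrupt, or schema-incompatible."""
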