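"""Exception hierarchy shared across the pipeline stages."""


class InteropinError(Exception):
    """Base class for all package errors."""


class FormatError(InteropinError):
    """A file does not conform to its declared dialect."""


class ConfigurationError(InteropinError):
    """A configuration value is out of range or self-contradictory."""


class MappingError(InteropinError):
    """An identifier-mapping table is inconsistent (e.g. conflicting rows)."""


class IdentifierMismatchError(InteropinError):
    """Inputs refer to different organisms or disjoint identifier spaces."""


class DuplicateOrganismError(InteropinError):
    """An organism was offered for integration twice."""


class LookupError_(InteropinError):
    """An identifier (GO term, protein) is absent from the graph/table."""


class UndatedError(InteropinError):
    """A presence row is all-absent, so no age group can be assigned."""
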