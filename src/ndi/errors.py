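"""Exception hierarchy shared by all subsystems."""


class NDIError(Exception):
    """Base class for all errors raised by this package."""


class SessionMetadataError(NDIError):
    """On-disk session metadata is missing, corrupted, or unreadable."""


class ConflictError(NDIError):
    """An item with the same identity already exists."""


class ValidationError(NDIError):
    """A document, probe map, or configuration failed validation."""

    def __init__(self, message, problems=None):
        super().__init__(message)
        self.problems = list(problems or [])


class SchemaError(NDIError):
    """A document schema definition is malformed or unresolvable."""


class DependencyError(NDIError):
    """A document dependency is dangling or blocks a removal."""


class UnknownDocumentError(NDIError):
    """No document with the requested identifier exists."""


class NoSuchChannelError(NDIError):
    """A requested DAQ channel does not exist in the epoch."""


class UnsupportedChannelError(NDIError):
    """The channel class is not supported by this reader kind."""


class NoTimeMappingError(NDIError):
    """No path exists in the synchronization graph between two time bases."""


class QueryError(NDIError):
    """A query predicate is malformed (bad regexp, unknown operator)."""
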