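"""Named exception types raised at the package's validation boundaries."""


class BBGraphError(ValueError):
    """Base class for all bbgraph validation errors."""


class EmptyInputError(BBGraphError):
    """A query or reference index set was empty."""


class ParameterError(BBGraphError):
    """A scalar parameter was outside its legal range."""


class BatchSizeError(BBGraphError):
    """A batch holds fewer cells than the requested per-batch neighbour count."""


class DomainError(BBGraphError):
    """Matrix entries fell outside their required domain."""


class AlignmentError(BBGraphError):
    """Sidecar files do not align with the matrix they describe."""


class SchemaError(BBGraphError):
    """A required column or field is missing from a metadata table."""
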