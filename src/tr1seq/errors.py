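"""Exception hierarchy for the tr1seq pipeline.

All errors derive from :class:`Tr1seqError` so callers can catch pipeline
failures with a single except clause; validation errors additionally derive
from ``ValueError`` so they behave sensibly in generic code.
"""


class Tr1seqError(Exception):
    """Base class for all tr1seq errors."""


class ParameterError(Tr1seqError, ValueError):
    """A configuration or function parameter is out of its allowed range."""


class InputError(Tr1seqError, ValueError):
    """A data input violates a precondition (empty pool, bad alphabet, ...)."""


class FormatError(Tr1seqError, ValueError):
    """A file does not conform to its declared interchange format."""


class StateError(Tr1seqError, RuntimeError):
    """An operation was invoked on an object in an invalid state."""


class AnnotationError(Tr1seqError, ValueError):
    """A germline segment lacks a required anchor annotation."""
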