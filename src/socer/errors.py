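"""Exception hierarchy.

``FormatError`` covers malformed input files and invariant violations at
parse time; ``DataError`` covers semantically invalid analysis requests
(e.g. a gene of interest missing from a table). Both derive from
``SocerError`` so callers can catch everything the package raises on bad
input with one clause.
"""


class SocerError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(SocerError):
    """A file or record violates the input format or a type invariant."""


class DataError(SocerError):
    """The inputs parse but the requested analysis is not valid on them."""
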