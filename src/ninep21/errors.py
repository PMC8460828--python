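"""Typed exceptions raised by validation and parsing.

Every malformed input raises one of these; nothing is silently coerced.
"""


class Ninep21Error(Exception):
    """Base class for all package errors."""


class ParseError(Ninep21Error):
    """A file could not be parsed (malformed header, non-numeric cell, ...)."""


class ValidationError(Ninep21Error):
    """A parsed table violates a domain invariant (duplicate ids, bad vocabulary, ...)."""


class AnalysisError(Ninep21Error):
    """An operation's preconditions are not met (missing gene, empty group, ...)."""
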