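"""Typed errors raised by input validation.

Malformed inputs always raise one of these; nothing is silently coerced.
"""


class DyscordError(Exception):
    """Base class for all package errors."""


class FormatError(DyscordError, ValueError):
    """A file does not conform to the expected layout (e.g. missing column)."""


class ValidationError(DyscordError, ValueError):
    """A structurally well-formed input violates a semantic invariant."""
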