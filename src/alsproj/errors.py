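"""Typed exceptions raised across the package.

Every malformed input raises one of these; nothing is silently fixed.
"""


class AlsProjError(Exception):
    """Base class for all package errors."""


class FormatError(AlsProjError):
    """A file does not follow the expected layout (missing column, bad label)."""


class ValidationError(AlsProjError):
    """Well-formed input violates a domain invariant (negative rate, overlap...)."""


class ConfigError(AlsProjError):
    """Inconsistent run configuration (region mismatch, unclassified region...)."""


class DomainError(AlsProjError):
    """Arguments outside an operation's mathematical domain."""


class RetrievalError(AlsProjError):
    """Remote population data could not be obtained and no cache exists."""
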