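"""Exception hierarchy.

``DataError`` covers anything wrong with user-supplied input (files,
matrices, partitions that do not cover the network).  ``ConfigError``
covers invalid algorithm parameters.  ``InternalError`` flags a breach of
an internal invariant and should never be seen by a correct caller.
"""


class CranioNetError(Exception):
    """Base class for all package errors."""


class DataError(CranioNetError):
    """Invalid input data: malformed matrix, mismatched node sets, ..."""


class ConfigError(CranioNetError):
    """Invalid algorithm configuration."""


class InternalError(CranioNetError):
    """An internal invariant was violated (a bug, not a user error)."""
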