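"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
"""


class RepleteAuditError(Exception):
    """Base class for all package errors."""


class ConfigError(RepleteAuditError):
    """Invalid or incomplete configuration (schema map, ranges, rules, paths)."""


class DataError(RepleteAuditError):
    """Input data violates a hard contract (missing column, rank deficiency...)."""
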