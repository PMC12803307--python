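"""Exception hierarchy.

Two failure families matter to callers: a misconfigured run (wrong column
mapping, bad flag values) and structurally invalid data (empty catalogue,
cyclic phenotype hierarchy, unparseable timestamps).  The CLI maps them to
exit codes 2 and 3 respectively.
"""


class IcdsemError(Exception):
    """Base class for all package errors."""


class ConfigurationError(IcdsemError):
    """A run was configured incorrectly (missing columns, bad parameters)."""


class DataError(IcdsemError):
    """Input data violates a structural requirement."""
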