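"""Exception hierarchy shared across olfnet modules.

The pipeline CLI maps these onto exit codes: configuration problems exit
with 2, data-integrity problems with 3.
"""


class OlfnetError(Exception):
    """Base class for all olfnet errors."""


class ConfigurationError(OlfnetError):
    """Invalid or inconsistent user-supplied configuration."""


class DataIntegrityError(OlfnetError):
    """Input data violate a structural invariant (asymmetry, negative
    times, mismatched labels, ...)."""


class UndefinedResultError(OlfnetError):
    """A requested statistic is mathematically undefined for the given
    input (e.g. a recognition index with zero total investigation time).
    Raised instead of silently returning 0, which would bias group means."""
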