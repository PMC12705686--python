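"""Exception hierarchy.

All replidyn errors derive from :class:`ReplidynError` so callers can catch
the package's failures with one clause; the subclasses distinguish bad
arguments, malformed input files, numerical failures and QC rejections.
"""


class ReplidynError(Exception):
    """Base class for all replidyn errors."""


class ArgumentError(ReplidynError, ValueError):
    """An argument violates a documented precondition."""


class StructuralError(ReplidynError):
    """Input data is malformed (bad grid, shape mismatch, duplicate ids)."""


class NumericError(ReplidynError):
    """A numerical routine failed to converge."""


class QCError(ReplidynError):
    """A cell or profile does not carry enough data to be analyzed."""
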