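"""Typed exceptions raised across the package.

Readers and statistical operations never return partially loaded or silently
degenerate results; they raise one of these instead.  The CLI maps each
category to a distinct nonzero exit code.
"""


class AmpscapeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AmpscapeError):
    """A generator or pipeline configuration violates its invariants."""


class FormatError(AmpscapeError):
    """An input file does not conform to its declared format."""


class InputError(AmpscapeError):
    """An argument violates an operation's precondition."""


class UndefinedRateError(AmpscapeError):
    """A rate was requested with a zero denominator."""


class EmptySubsetError(AmpscapeError):
    """A conditioning subset (e.g. anchor-amplified cases) is empty."""


class DegenerateCellError(AmpscapeError):
    """A cell with zero total counts cannot be normalized."""


class GroupingError(AmpscapeError):
    """A two-group comparison was requested with an empty group."""
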