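"""Exception hierarchy for collagetex.

All package-specific failures derive from :class:`CollagetexError` so callers
can catch one base class at tool boundaries.
"""


class CollagetexError(Exception):
    """Base class for all collagetex errors."""


class InputError(CollagetexError):
    """Unreadable or malformed input file."""


class UnsupportedFormatError(InputError):
    """File format or layout the package deliberately does not handle
    (e.g. >3 spatial axes, multi-channel images without a selected channel)."""


class AlignmentError(CollagetexError):
    """Grids of an image and a mask (or two maps) do not match."""


class EmptyROIError(CollagetexError):
    """A region of interest contains no member locations."""


class DegenerateInputError(CollagetexError):
    """Input too small or otherwise degenerate for the requested operation."""


class NumericalInputError(CollagetexError):
    """Non-finite values where finite numbers are required."""


class ConfigError(CollagetexError):
    """Invalid configuration value."""


class NoPairsError(CollagetexError):
    """A co-occurrence window contains no location pairs."""


class GroupingError(CollagetexError):
    """Cross-validation grouping cannot be satisfied (fewer groups than folds)."""


class UndefinedAUCError(CollagetexError):
    """ROC AUC requested with only one class present."""
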