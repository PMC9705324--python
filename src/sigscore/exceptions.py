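"""Exception hierarchy.

All package-specific failures derive from :class:`SigscoreError` so callers can
catch one base class; the subclasses also derive from :class:`ValueError`
because they signal invalid inputs rather than internal faults.
"""


class SigscoreError(Exception):
    """Base class for all sigscore errors."""


class ConfigurationError(SigscoreError, ValueError):
    """Invalid simulator or pipeline configuration."""


class DataFormatError(SigscoreError, ValueError):
    """Malformed input file (expression table, GMT, MatrixMarket bundle...)."""


class EmptyIntersectionError(SigscoreError, ValueError):
    """A gene set shares no members with the ranked list / matrix."""


class GroupingError(SigscoreError, ValueError):
    """Sample groups missing, too small, or otherwise unusable for a test."""


class StratificationError(SigscoreError, ValueError):
    """Too few usable response grades for a stratified comparison."""
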