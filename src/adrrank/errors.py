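"""Exception hierarchy shared across the package."""


class AdrRankError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AdrRankError):
    """A file is structurally unreadable (missing header, missing column, empty)."""


class DataError(AdrRankError):
    """Input rows are structurally fine but semantically inconsistent."""


class ConfigError(AdrRankError):
    """A parameter combination is invalid."""


class IntegrityError(AdrRankError):
    """An internal invariant of a result object is violated."""
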