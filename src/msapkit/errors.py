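"""Exception hierarchy shared across the toolkit."""


class MsapError(Exception):
    """Base class for all msapkit errors."""


class InvalidObservationError(MsapError):
    """A band call or pattern quad contains a non-binary value."""


class EmptyInputError(MsapError):
    """An operation received no usable (non-missing, non-ambiguous) data."""


class DegenerateTableError(MsapError):
    """A contingency table has a zero row or column margin."""


class UndefinedResidualError(MsapError):
    """An adjusted residual is undefined (a margin equals the grand total)."""


class InvalidPositionError(MsapError):
    """A reference position is out of range or does not hold a cytosine."""


class LowQualityAlignmentError(MsapError):
    """Pairwise alignment identity fell below the configured floor."""


class IncompatibleReportError(MsapError):
    """Two methylation reports do not share the same reference."""


class InsufficientDataError(MsapError):
    """Not enough complete replicates to compute a fold change."""


class ConfigError(MsapError):
    """A simulation or run configuration failed validation."""


class ParseError(MsapError):
    """An input file could not be parsed."""
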