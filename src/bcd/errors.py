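"""Typed exceptions.

Degenerate inputs raise rather than returning sentinels so that the
matrix-screening layer can count and log skipped analytes by reason.
"""


class BCDError(ValueError):
    """Base class for all package errors."""


class TooFewValuesError(BCDError):
    """Fewer values than the statistic requires (moments need n >= 2,
    the bimodality coefficient needs n >= 4 for its size correction)."""


class ConstantInputError(BCDError):
    """All values identical: variance is zero and skewness/kurtosis,
    hence BC, min/max normalization and fold change, are undefined."""


class GroupInputError(BCDError):
    """A per-group statistic failed; carries which group was at fault."""

    def __init__(self, group: str, cause: BCDError):
        self.group = group
        self.cause = cause
        super().__init__(f"{group}: {cause}")


class UndefinedFoldChangeError(BCDError):
    """A group's central tendency is not strictly positive, so the
    log2 ratio is undefined (fold change is unstable near zero)."""


class EmptyGroupError(BCDError):
    """A case or control group contains no values."""


class UnknownCovariateError(BCDError):
    """Requested covariate column is absent from the phenotype table."""


class EmptySelectionError(BCDError):
    """A sample filter removed every sample (or every case / control)."""


class MatrixFormatError(BCDError):
    """Expression or phenotype file violates the expected dialect."""
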