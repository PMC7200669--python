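"""Exception types raised across the package."""


class MpbSelectError(Exception):
    """Base class for all package errors."""


class InvalidRangeError(MpbSelectError):
    """A covariate field range has min > max."""


class UnknownCovariateError(MpbSelectError):
    """A coefficient or subset references a covariate that does not exist."""


class MissingColumnsError(MpbSelectError):
    """A table is missing required columns; `.columns` lists the absent names."""

    def __init__(self, columns):
        self.columns = sorted(columns)
        super().__init__(f"missing required columns: {', '.join(self.columns)}")


class DegenerateBorderError(MpbSelectError):
    """The border polyline has zero length or fewer than two vertices."""


class RingIndexError(MpbSelectError):
    """Neighborhood ring index outside {1, 2, 3}."""


class OutOfGridError(MpbSelectError):
    """A cell index falls outside the grid."""


class YearGapError(MpbSelectError):
    """The census years are not contiguous."""


class PhasePartitionError(MpbSelectError):
    """Phase ranges have gaps, overlaps, or a phase would be empty."""


class RankDeficientError(MpbSelectError):
    """The design matrix has perfectly collinear columns."""


class DegenerateResponseError(MpbSelectError):
    """The binary response contains a single class."""


class NotConvergedError(MpbSelectError):
    """An operation requires a converged fit."""


class ZeroVarianceError(MpbSelectError):
    """A covariate with zero variance cannot be z-scored."""


class EnumerationCapError(MpbSelectError):
    """Too many candidate covariates for exhaustive enumeration."""


class PhenologySeriesError(MpbSelectError):
    """A daily temperature series does not cover the required days."""
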