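"""Exception hierarchy for subsetvi."""


class SubsetVIError(Exception):
    """Base class for all subsetvi errors."""


class RankDeficiencyError(SubsetVIError):
    """A normal-equations subsystem is numerically singular.

    Raised when a Cholesky pivot falls below the relative tolerance; the
    message names the offending column where it can be identified.
    """


class DegenerateFitError(SubsetVIError):
    """Residual sum of squares is numerically zero or negative.

    Perfect fits are unsupported: the profile Gaussian likelihood diverges
    as the error variance estimate goes to zero.
    """


class ZeroVarianceError(SubsetVIError):
    """A predictor column is constant and cannot be standardized."""


class InvalidPenaltyError(SubsetVIError, ValueError):
    """Penalty specification is inconsistent or out of range."""


class SearchSizeError(SubsetVIError):
    """Exhaustive enumeration was requested for too many free variables."""


class ConsistencyError(SubsetVIError):
    """Objects built under different penalties/settings were combined."""


class TableReadError(SubsetVIError, ValueError):
    """A data table could not be parsed into a numeric dataset."""
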