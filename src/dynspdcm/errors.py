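"""Named exception types raised across the package."""


class DynSpDCMError(Exception):
    """Base class for all package errors."""


class MissingFileError(DynSpDCMError):
    """Input file does not exist."""


class EmptyTimeSeriesError(DynSpDCMError):
    """Time-series file contains a header but no scans."""


class RaggedRowsError(DynSpDCMError):
    """Rows of a delimited time-series file have unequal length."""


class NonNumericCellError(DynSpDCMError):
    """A body cell of a time-series file could not be parsed as a number."""


class DuplicateRegionError(DynSpDCMError):
    """Region names in the header are not unique."""


class WindowExceedsSeriesError(DynSpDCMError):
    """Requested window length is longer than the series."""


class DegenerateSeriesError(DynSpDCMError):
    """Series is unusable for spectral fitting (e.g. a constant channel)."""


class AliasedFrequencyError(DynSpDCMError):
    """A requested frequency lies above the Nyquist frequency."""


class UnstableSystemError(DynSpDCMError):
    """Effective connectivity matrix has an eigenvalue with non-negative real part."""


class NumericalFailureError(DynSpDCMError):
    """NaN/Inf encountered in gradients or curvatures during optimisation."""


class SingularDesignError(DynSpDCMError):
    """Second-level design matrix is rank deficient."""


class RankDeficientError(DynSpDCMError):
    """Requested more basis columns than the data support."""
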