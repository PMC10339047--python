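"""Exception hierarchy for metabomr.

Every error raised deliberately by this package derives from
:class:`MetaboMRError`, so callers can catch one type at pipeline level.
"""


class MetaboMRError(Exception):
    """Base class for all metabomr errors."""


class FormatError(MetaboMRError):
    """A delimited input file is missing mandatory columns or is malformed."""


class EmptyInputError(MetaboMRError):
    """No valid rows survived input validation."""


class EmptyInstrumentError(MetaboMRError):
    """No variant passed the instrument-selection p-value threshold."""


class EmptyHarmonizationError(MetaboMRError):
    """Every variant was dropped during exposure/outcome harmonization."""


class InsufficientInstrumentsError(MetaboMRError):
    """Fewer variants than the estimator's minimum (e.g. Egger needs k >= 3)."""


class DegenerateInstrumentError(MetaboMRError):
    """A per-variant ratio is undefined (exposure beta of zero)."""


class CollinearityError(MetaboMRError):
    """Design matrix is rank deficient / has no spread."""


class VariantLookupError(MetaboMRError):
    """A variant id is absent from the LD matrix or a summary-stat table."""


class BoundaryError(MetaboMRError):
    """A profile-likelihood maximum sits on the search-grid boundary."""


class NoValidSubsetError(MetaboMRError):
    """MVMR-Lasso found no valid instrument subset large enough to fit."""


class InputError(MetaboMRError):
    """Generic invalid argument (bad matrix, unknown category code, ...)."""


class ConvergenceError(MetaboMRError):
    """An iterative fit failed to converge."""
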