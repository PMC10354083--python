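"""Exception hierarchy for the urban-tolerance pipeline."""


class UrbantolError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(UrbantolError):
    """Invalid configuration value (non-positive extent, pixel size, ...)."""


class SchemaError(UrbantolError):
    """An input table is missing a required column."""


class AlignmentError(UrbantolError):
    """Raster stack members do not share grid geometry."""


class ExtentError(UrbantolError):
    """A query point lies outside the raster extent."""


class CoverageError(UrbantolError):
    """A buffer contains no usable (non-nodata) pixels."""


class EmptyRangeError(UrbantolError):
    """A range-clip was requested with an empty polygon set."""


class RankError(UrbantolError):
    """Too few distinct covariate values to build the requested basis."""


class DomainError(UrbantolError):
    """Covariate values outside the domain of a basis (e.g. cyclic period)."""


class DegenerateResponseError(UrbantolError):
    """Response vector unusable for fitting (e.g. all zeros)."""


class InsufficientDataError(UrbantolError):
    """Too few rows remain after covariate-completeness filtering."""


class UnstableEstimateError(UrbantolError):
    """Too few resampling runs converged to report an index."""


class DegenerateScaleError(UrbantolError):
    """A vector with no variation cannot be z-scored."""
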