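"""Exception hierarchy for the spermdfi package."""


class SpermDFIError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SpermDFIError, ValueError):
    """Invalid configuration (fractions, sds, counts...)."""


class GenerationError(SpermDFIError, RuntimeError):
    """Synthetic geometry cannot be rendered (e.g. shape exceeds raster)."""


class NoCellFound(SpermDFIError, RuntimeError):
    """No sperm head above the minimum area was found in a brightfield image."""


class MeasurementError(SpermDFIError, RuntimeError):
    """A measurement could not be taken (degenerate mask, empty region)."""


class DomainError(SpermDFIError, ValueError):
    """Numeric input outside the mathematical domain of an operation."""


class UndefinedDFI(SpermDFIError, ValueError):
    """DFI is undefined because red + green intensity is zero."""


class SchemaError(SpermDFIError, ValueError):
    """A table is missing required columns or has malformed labels."""


class ValidationError(SchemaError):
    """A table value violates its documented range (e.g. DFI outside [0, 1])."""


class RankError(SpermDFIError, ValueError):
    """Rank-deficient design matrix; message names the collinear terms."""


class TrainingError(SpermDFIError, RuntimeError):
    """Neural-network training produced a non-finite loss."""


class ClassBalanceError(SpermDFIError, ValueError):
    """A classification training set contains a single class."""


class DegenerateInput(SpermDFIError, ValueError):
    """Statistic undefined on this input (constant vector, single class...)."""
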