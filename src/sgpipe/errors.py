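"""Exception and warning hierarchy for sgpipe."""


class SGPipeError(Exception):
    """Base class for all sgpipe errors."""


class InvalidArgumentError(SGPipeError, ValueError):
    """An argument violates a documented precondition."""


class MissingDataError(SGPipeError):
    """A required record (weather day, anthesis date, ...) is absent."""


class CalibrationError(SGPipeError):
    """Panel calibration impossible (empty region or non-positive panel mean)."""


class InvalidDefinitionError(SGPipeError, ValueError):
    """A spectral-index definition references a band absent from the stack."""


class InvalidPlotMapError(SGPipeError, ValueError):
    """Plot polygons overlap or fall outside the raster."""


class InvalidPlotError(SGPipeError, ValueError):
    """A single plot rectangle is outside the raster bounds."""


class InfeasibleGradientError(SGPipeError, ValueError):
    """An era-frequency target cannot be met with the available carriers."""


class UndefinedBaselineError(SGPipeError, ValueError):
    """Anthesis index value is non-positive; RSS is undefined."""


class InvalidATError(SGPipeError, ValueError):
    """Accumulated temperature non-positive where a ratio requires it."""


class InsufficientEnvironmentsError(SGPipeError, ValueError):
    """Heritability needs at least two environments."""


class EmptyResultError(SGPipeError):
    """No pairs/windows/records satisfy the query."""


class DegenerateKinshipError(SGPipeError, ValueError):
    """No polymorphic SNPs available to build a relatedness matrix."""


class CollinearityError(SGPipeError, ValueError):
    """Covariate block is singular in the mixed-model fit."""


class InvalidConfigError(SGPipeError, ValueError):
    """A configuration value is out of range (e.g. non-positive p cutoff)."""


class NoSNPsError(SGPipeError):
    """A genomic interval contains no SNP passing filters."""


class InvalidPartitionError(SGPipeError, ValueError):
    """A two-population partition is empty or not disjoint."""


class InvalidDriftVarianceError(SGPipeError, ValueError):
    """Genome-wide drift variance estimate is non-positive."""


class MissingSNPError(SGPipeError, KeyError):
    """A requested SNP id is not present in the genotype matrix."""


class InsufficientGroupError(SGPipeError, ValueError):
    """A haplotype group has fewer than two members for a t-test."""


class StageUnresolvedWarning(UserWarning):
    """No flight within the AT tolerance of a stage boundary."""


class EmptyPlotWarning(UserWarning):
    """A plot has no masked pixels; its value is set to missing."""


class UndefinedCorrelationWarning(UserWarning):
    """A trait column is constant; its correlations are undefined."""


class ReducedRankWarning(UserWarning):
    """Requested number of PCs exceeds the matrix rank; k was reduced."""
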