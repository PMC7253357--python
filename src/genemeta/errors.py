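"""Exception hierarchy for genemeta.

All package-specific failures derive from :class:`GeneMetaError` so callers
can catch one base class. Subclasses are narrow and named for the contract
they enforce.
"""


class GeneMetaError(Exception):
    """Base class for all genemeta errors."""


class SchemaError(GeneMetaError):
    """An input table is missing a required column."""


class CountError(GeneMetaError, ValueError):
    """A genotype count is negative or not an integer."""


class UnavailableContrastError(GeneMetaError):
    """The phenotype contrast names an arm absent from the study record."""


class UnsupportedModelError(GeneMetaError):
    """The genetic model has no single 2x2 collapse (additive)."""


class DegenerateInputError(GeneMetaError):
    """An arm or table total is zero where a positive total is required."""


class ZeroCellError(GeneMetaError):
    """A 2x2 cell is zero under the 'none' continuity-correction policy."""


class InsufficientStudiesError(GeneMetaError):
    """Fewer studies than the operation's minimum k."""


class SingularDesignError(GeneMetaError):
    """Regression design matrix is singular (e.g. all precisions equal)."""


class UndefinedRatioError(GeneMetaError):
    """Mantel-Haenszel denominator sum is zero."""


class ConvergenceError(GeneMetaError):
    """An iterative procedure failed to stabilise within its iteration cap."""


class MetadataError(GeneMetaError):
    """A study record lacks metadata (e.g. year) required by the analysis."""


class PipelineError(GeneMetaError):
    """No analysis could be run for the given configuration."""
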