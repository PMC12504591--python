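"""Exception hierarchy.

Every error the library raises derives from :class:`SilvocarbonError`, so
callers (and the CLI) can catch one base class. Subclasses map onto the
distinct failure modes of the pipeline: malformed input files, invalid
values, misaligned rasters, distribution/config mistakes, degenerate
statistical input, and missing carbon-density coverage.
"""


class SilvocarbonError(Exception):
    """Base class for all silvocarbon errors."""


class FormatError(SilvocarbonError):
    """An input file does not have the expected structure (missing columns...)."""


class ValidationError(SilvocarbonError):
    """A value violates a domain invariant (negative area, unknown category...)."""


class AlignmentError(SilvocarbonError):
    """Two grids that must be pixel-aligned are not (shape/nodata/cell-area)."""


class ConfigError(SilvocarbonError):
    """A configuration value is out of range or a distribution is invalid."""


class DomainError(SilvocarbonError):
    """A biophysical parameter is outside its physical domain."""


class DegenerateSampleError(SilvocarbonError):
    """A statistic was requested on a sample too small or with zero variance."""


class FilterCollapseError(SilvocarbonError):
    """Outlier filtering would remove all (or an implausible share of) a sample."""


class ZeroVarianceError(SilvocarbonError):
    """Sensitivity indices requested for a model output with zero variance."""


class CoverageError(SilvocarbonError):
    """A populated LULC category has no carbon-density range."""


class UndefinedBaselineError(SilvocarbonError):
    """A percent change was requested against a zero baseline."""
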