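"""Exception hierarchy shared across the package.

All user-facing failures derive from :class:`GrnTrendError` so callers (and
the CLI) can distinguish configuration, data and pipeline problems.
"""


class GrnTrendError(Exception):
    """Base class for all package errors."""


class FormatError(GrnTrendError, ValueError):
    """A file does not conform to its declared on-disk format."""


class DataError(GrnTrendError, ValueError):
    """File parsed, but the content violates a domain invariant."""


class ParameterError(GrnTrendError, ValueError):
    """A parameter value is outside its admissible range."""


class PipelineError(GrnTrendError, RuntimeError):
    """A pipeline stage cannot proceed (e.g. zero cells survive QC)."""


class DegenerateTimeError(PipelineError):
    """Group pseudotimes carry no variance, so trend slopes are undefined."""


class DegenerateGeometryError(PipelineError):
    """Embedding covariance is singular; Mahalanobis ranking is undefined."""


class GeneLookupError(GrnTrendError, KeyError):
    """A requested gene identifier is not present in the matrix."""
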