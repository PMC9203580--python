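"""Exception hierarchy shared across the package.

All domain errors derive from :class:`EqtlAtlasError` so callers can catch
package failures without masking programming errors.
"""


class EqtlAtlasError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(EqtlAtlasError, ValueError):
    """A simulation or analysis configuration violates its invariants."""


class FormatError(EqtlAtlasError, ValueError):
    """An on-disk file cannot be parsed or violates its format contract."""


class MetadataError(FormatError):
    """Sample metadata is inconsistent with a data matrix."""


class EmptyInputError(EqtlAtlasError, ValueError):
    """An operation received an input with no usable records."""


class NormalizationError(EqtlAtlasError, ValueError):
    """No reference transcript is usable for median-of-ratios factors."""


class ConvergenceError(EqtlAtlasError, RuntimeError):
    """An iterative procedure failed to reach a fixed point."""


class DegenerateInputError(EqtlAtlasError, ValueError):
    """Input is degenerate for the requested estimator (e.g. zero variance)."""
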