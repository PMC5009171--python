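"""Exception types shared across the package."""


class TractConcordError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TractConcordError):
    """Invalid configuration (bad grid, degenerate geometry, bad params)."""


class SectioningError(TractConcordError):
    """Sectioning geometry impossible (spacing exceeds volume extent)."""


class DeformationError(TractConcordError):
    """Requested deformation folds (non-positive Jacobian) and could not
    be regenerated within the retry budget."""


class DegenerateLandmarksError(TractConcordError):
    """Too few or collinear landmark pairs for an affine fit."""


class DivergenceError(TractConcordError):
    """Nonlinear refinement cost increased for several consecutive
    iterations."""


class NormalizationError(TractConcordError):
    """Connectivity-map normalization undefined (zero accepted
    streamlines)."""


class UndefinedRateError(TractConcordError):
    """TPR or FPR undefined because a confusion-count denominator is
    zero."""


class GridMismatchError(TractConcordError):
    """Reports to be averaged do not share the same (roi, threshold)
    grid."""


class FormatError(TractConcordError):
    """Malformed or unsupported file content (bad header, anisotropic
    spacing where isotropy is required, ...)."""
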