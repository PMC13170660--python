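"""Exception hierarchy.

Every pipeline stage rejects inputs violating its preconditions with one of
these, rather than silently coercing.  All inherit from :class:`PipelineError`
so callers (and the CLI) can catch validation failures uniformly.
"""


class PipelineError(Exception):
    """Base class for all iglonquant errors."""


class InvalidParameterError(PipelineError, ValueError):
    """A parameter violates a stage precondition (negative rate, bad taus, ...)."""


class WindowTooLongError(InvalidParameterError):
    """Baseline window exceeds the trace duration."""


class DegenerateBaselineError(PipelineError):
    """Baseline F0 is non-positive; ΔF/F0 undefined."""


class InsufficientControlError(PipelineError):
    """Fewer than two control neurons; mean + 2·SD threshold undefined."""


class LabelMismatchError(PipelineError):
    """Rates and threshold come from different timepoints."""


class DegenerateReferenceError(PipelineError):
    """Normalization reference group has zero mean rate."""


class InvalidRoiError(PipelineError):
    """ROI masks violate invariants (nucleus not inside soma, shape mismatch)."""


class DegenerateRoiError(InvalidRoiError):
    """Soma and nucleus areas coincide; cytoplasmic mean undefined."""


class EmptyMaskError(PipelineError):
    """A required segmentation mask is empty (e.g. MAP2+ area = 0)."""


class InsufficientDataError(PipelineError):
    """Too few distinct points to fit (one-site fit needs ≥ 3 concentrations)."""


class GenerationError(PipelineError):
    """A synthetic fixture could not be generated under its constraints."""


class FormatError(PipelineError):
    """A file does not conform to the expected on-disk format."""
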