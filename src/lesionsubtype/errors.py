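"""Exception hierarchy shared across the pipeline stages."""


class LesionSubtypeError(Exception):
    """Base class for all package-specific errors."""


class SizingError(LesionSubtypeError):
    """Grid too small to host the requested anatomy."""


class ShapeError(LesionSubtypeError):
    """Arrays that must share a grid do not."""


class ConfigurationError(LesionSubtypeError):
    """Invalid or unachievable configuration (e.g. prevalence calibration)."""


class ArgumentError(LesionSubtypeError):
    """Invalid argument value."""


class RangeError(ArgumentError):
    """Scalar outside its documented range."""


class AlignmentError(LesionSubtypeError):
    """Subject-aligned inputs are misaligned or of unequal length."""


class DegenerateLabelError(LesionSubtypeError):
    """Labels contain a single class where two are required."""


class ArchitectureError(LesionSubtypeError):
    """Network structure incompatible with the input grid."""


class DivergenceError(LesionSubtypeError):
    """Training produced a non-finite loss."""


class TuningError(LesionSubtypeError):
    """Every tuning candidate failed."""


class CoverageError(LesionSubtypeError):
    """A per-subject artifact (e.g. saliency map) is missing for some subject."""


class NormalizationError(LesionSubtypeError):
    """Map cannot be normalized (zero total mass)."""


class UndefinedSimilarityError(LesionSubtypeError):
    """Similarity undefined (e.g. both maps constant)."""


class SelectionError(LesionSubtypeError):
    """Model-order selection had no admissible candidate."""


class ConvergenceError(LesionSubtypeError):
    """Iterative algorithm failed to converge."""


class DependencyError(LesionSubtypeError):
    """A pipeline stage is missing or has corrupted upstream output."""


class ReportError(LesionSubtypeError):
    """Results directory holds nothing to summarize."""
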