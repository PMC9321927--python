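"""Exception hierarchy.

Every operation raises a subclass of :class:`ColdLocusError` for domain
errors, so callers can catch one type at the CLI boundary.
"""


class ColdLocusError(Exception):
    """Base class for all coldlocus domain errors."""


class GeneNotFoundError(ColdLocusError):
    """Requested gene id absent from the annotation."""


class MalformedAnnotationError(ColdLocusError):
    """Annotation violates structural expectations (e.g. overlapping exons)."""


class EmptyIntronError(ColdLocusError):
    """Intron extraction requested for a single-exon gene."""


class BoundsError(ColdLocusError):
    """Interval extends beyond the sequence it indexes."""


class AlphabetError(ColdLocusError):
    """Sequence contains characters outside the expected alphabet."""


class EmptyInputError(ColdLocusError):
    """Operation requires a non-empty input."""


class ConfigError(ColdLocusError):
    """Invalid parameter value (wrong hexamer length, mismatch budget...)."""


class StructureError(ColdLocusError):
    """Tabular input with inconsistent structure (unequal intron counts...)."""


class GroupingError(ColdLocusError):
    """Grouped alignment lacks a required group."""


class MatrixError(ColdLocusError):
    """Distance matrix invalid (asymmetric beyond tolerance, bad shape)."""


class UndefinedDistanceError(ColdLocusError):
    """No comparable (gap-free in both) sites between two aligned sequences."""


class PatternNotFoundError(ColdLocusError):
    """Required sequence pattern absent (e.g. <2 cysteines in a domain)."""


class PairingError(ColdLocusError):
    """Cq table lacks the calibrator tissue or a gene for some specimen."""


class SpecError(ColdLocusError):
    """Synthetic-data spec is internally inconsistent or infeasible."""
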