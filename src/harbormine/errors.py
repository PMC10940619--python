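"""Exception hierarchy shared across the package."""


class HarbormineError(Exception):
    """Base class for all package-specific errors."""


class GFF3ParseError(HarbormineError):
    """A GFF3 line could not be parsed; message carries the line number."""


class AnnotationValidationError(HarbormineError):
    """An annotation violates an invariant (duplicate ID, out-of-range gene)."""


class CountTableError(HarbormineError):
    """A count table is malformed (negative/non-integer cell, missing columns)."""


class OutOfBoundsError(HarbormineError):
    """A requested genomic window extends past a chromosome end."""


class EmptyPromoterError(HarbormineError):
    """A divergent pair has abutting genes and no promoter interval."""


class TemplateDesignError(HarbormineError):
    """A fixing template cannot be built (flank shorter than arm/repeat)."""


class IntegrationError(HarbormineError):
    """Homology arms do not match the genome at the target locus (failed HDR)."""


class LoopOutImpossibleError(HarbormineError):
    """No identical direct repeats flank the marker; 5-FOA counter-selection
    would kill the strain instead of excising the marker."""


class SimulationConfigError(HarbormineError):
    """A simulation configuration is infeasible (genes do not fit, etc.)."""
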