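"""Exception hierarchy for the dosimetry pipeline."""


class SirtDoseError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(SirtDoseError):
    """Phantom compartments overlap or a required compartment is missing."""


class DegenerateInputError(SirtDoseError):
    """An input carries no information (e.g. zero total activity)."""


class EmptyVOIError(SirtDoseError):
    """Requested compartment label is absent from the label grid."""


class UndefinedLSFError(SirtDoseError):
    """Lung shunt fraction is 0/0 (no counts in lungs or liver)."""


class ApportionmentError(SirtDoseError):
    """Activity cannot be apportioned (no liver counts while LSF < 1)."""


class UndefinedDoseError(SirtDoseError):
    """Absorbed dose is undefined (zero compartment mass)."""


class PlanningError(SirtDoseError):
    """Activity planning is impossible (e.g. no tumor uptake)."""


class PatientExcludedError(SirtDoseError):
    """Lung shunt fraction exceeds the exclusion threshold for treatment."""
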