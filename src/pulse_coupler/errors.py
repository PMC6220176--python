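"""Exception types shared across the pipeline."""


class PulseCouplerError(Exception):
    """Base class for all package errors."""


class InvalidInputError(PulseCouplerError):
    """Inputs violate a documented precondition (shape, range, alignment)."""


class InvalidGridError(InvalidInputError):
    """Spatial grid too small or inconsistent."""


class NumericalInstabilityError(PulseCouplerError):
    """An integrator produced non-finite values; names the offending step."""


class NoRestStateError(PulseCouplerError):
    """No stable uniform fixed point found for the given parameters."""


class SegmentationFailureError(PulseCouplerError):
    """Cell segmentation produced an empty foreground."""


class InvalidMaskError(InvalidInputError):
    """A per-frame mask is empty or inconsistent; names the frame."""


class InvalidConfigError(InvalidInputError):
    """A configuration block is inconsistent or incomplete."""


class InsufficientDataError(PulseCouplerError):
    """Too few observations for the requested statistic."""
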