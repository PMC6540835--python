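"""Exception hierarchy."""


class ApexDSError(Exception):
    """Base class for all apexds errors."""


class ValidationError(ApexDSError):
    """Input data or configuration violates the documented schema."""


class InsufficientDataError(ApexDSError):
    """Too few detections (or transects) to attempt the requested fit."""


class FitError(ApexDSError):
    """Optimizer failed to converge or produced an unusable fit."""


class NumericalError(ApexDSError):
    """Quadrature or linear-algebra failure with diagnostics attached."""
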