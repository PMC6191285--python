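"""Exception hierarchy shared across granulekit."""


class GranuleKitError(Exception):
    """Base class for all granulekit errors."""


class ParameterError(GranuleKitError, ValueError):
    """A parameter violates its documented domain."""


class OverlapError(GranuleKitError):
    """Requested granules overlap, which would corrupt per-granule truth."""


class PlacementError(GranuleKitError):
    """Objects could not be placed without overlap in the available space."""


class ProfileError(GranuleKitError):
    """Line-profile measurement failed."""


class NoGranuleOnProfileError(ProfileError):
    """No pixel on the profile exceeds the background threshold."""


class AmbiguousProfileError(ProfileError):
    """Several disjoint supra-threshold runs on one profile."""


class NormalizationError(GranuleKitError):
    """Recovery-trace normalization is undefined (e.g. no bleach depth)."""


class NoRecoveryError(GranuleKitError):
    """The curve shows no fluorescence recovery; the exponential fit is undefined."""


class FitConvergenceError(GranuleKitError):
    """Nonlinear least squares did not converge."""

    def __init__(self, message, p0=None, residual_norm=None):
        super().__init__(message)
        self.p0 = p0
        self.residual_norm = residual_norm


class TraceFormatError(GranuleKitError):
    """A trace table violates the documented CSV contract."""
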