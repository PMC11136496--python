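"""Exception types shared across the pipeline stages."""


class EhtKitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EhtKitError, ValueError):
    """Invalid configuration (negative length, window larger than stack, ...)."""


class GeometryError(EhtKitError, ValueError):
    """Degenerate geometry: zero-area polygon, ring with fewer than 3 points."""


class NoRingFound(EhtKitError, RuntimeError):
    """Wall signal below detectability on a slice; no ring could be fitted."""


class PavingError(EhtKitError, ValueError):
    """Seed ROIs overlap beyond tolerance and cannot form a joint paving."""

    def __init__(self, message, offending_ids=()):
        super().__init__(message)
        self.offending_ids = tuple(offending_ids)


class AssemblyError(EhtKitError, ValueError):
    """FRAP phase recordings missing, overlapping or non-monotone in time."""


class NoBleachDetected(EhtKitError, ValueError):
    """Post-bleach intensity never drops below the prebleach level."""


class NonPositivePrebleach(EhtKitError, ValueError):
    """Background-subtracted prebleach mean is not positive."""


class FitFailed(EhtKitError, RuntimeError):
    """No start of the recovery fit converged."""


class WindowError(EhtKitError, ValueError):
    """Requested analysis window does not contain enough samples."""
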