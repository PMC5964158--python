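"""Exception hierarchy for the repe toolkit."""


class RepeError(Exception):
    """Base class for all toolkit errors."""


class ParameterError(RepeError, ValueError):
    """Invalid user-supplied parameter (non-positive thickness, bad seed, ...)."""


class SegmentationError(RepeError, RuntimeError):
    """Thresholding / component extraction produced an empty or invalid mask."""


class RegistrationError(RepeError, RuntimeError):
    """Affine estimation failed (degenerate mask support, no overlap)."""


class TransformError(RepeError, ValueError):
    """Singular or otherwise unusable spatial transform."""


class GeometryError(RepeError, RuntimeError):
    """Surface or polygon construction violated a geometric contract."""


class ProjectionError(RepeError, ValueError):
    """A point could not be projected onto the scalp surface."""


class PlacementError(RepeError, RuntimeError):
    """Electrode footprint incompatible with the requested placement."""


class SolverError(RepeError, RuntimeError):
    """Field solver failed to converge within the iteration cap."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class ConfigError(RepeError, ValueError):
    """Invalid configuration (unknown tissue label, missing seed, ...)."""
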