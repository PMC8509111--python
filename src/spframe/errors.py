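"""Exception hierarchy for frame/localizer computations."""


class SpframeError(Exception):
    """Base class for all spframe errors."""


class ConfigError(SpframeError, ValueError):
    """Invalid frame or scenario configuration."""


class DegenerateGeometryError(SpframeError):
    """Geometry admits no meaningful answer (e.g. rod parallel to plane)."""


class OutOfExtentError(SpframeError):
    """A scan plane misses a rod: the intersection lies beyond the rod ends."""


class OffPlaneError(SpframeError):
    """A 3D point handed to the image chart does not lie on the scan plane."""


class DegenerateInputError(SpframeError):
    """Measured fiducials too close to the localizer apex to invert."""


class SolverFailureError(SpframeError):
    """No admissible real solution of the three-distance system.

    Carries the candidate residuals so callers can log or count the
    failure without re-deriving it.
    """

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals
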