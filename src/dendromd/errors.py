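"""Exception hierarchy."""


class DendroError(Exception):
    """Base class for all package errors."""


class InvalidRecipeError(DendroError):
    """Unsupported dendrimer family / generation / representation."""


class EmbeddingError(DendroError):
    """Initial-coordinate construction failed to resolve a steric clash."""

    def __init__(self, message, clashing_pair=None):
        super().__init__(message)
        self.clashing_pair = clashing_pair


class ParameterizationError(DendroError):
    """A bonded or non-bonded type present in the topology has no parameters."""


class DivergedTrajectoryError(DendroError):
    """Coordinates or forces overflowed during integration."""

    def __init__(self, message, last_stable_frame=None):
        super().__init__(message)
        self.last_stable_frame = last_stable_frame


class TrajectoryMismatchError(DendroError):
    """Trajectory file does not match the supplied topology or metadata."""


class ConstantSignalError(DendroError):
    """Autocorrelation requested for a zero-variance series."""


class EmptyLayerError(DendroError):
    """Layer statistics requested for a layer with no tracked atoms."""


class EmptySpectrumError(DendroError):
    """All relaxation-time samples of a layer are censored."""


class ResolutionError(DendroError):
    """Frame spacing too coarse for the requested dwell criterion."""
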