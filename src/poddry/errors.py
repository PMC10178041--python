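"""Exception hierarchy for poddry."""


class PoddryError(Exception):
    """Base class for all poddry errors."""


class DomainError(PoddryError, ValueError):
    """An input lies outside the physically valid range of a correlation."""


class ConfigError(PoddryError, ValueError):
    """A configuration file or block is invalid."""


class MeshError(PoddryError, ValueError):
    """Mesh generation failed or produced an invalid mesh."""


class EstimationError(PoddryError, RuntimeError):
    """The diffusivity estimator cannot produce a defined estimate."""


class CalibrationError(PoddryError, RuntimeError):
    """The surface-parameter calibration failed to bracket or converge."""


class NumericalError(PoddryError, RuntimeError):
    """A transient solve diverged or produced non-finite fields."""
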