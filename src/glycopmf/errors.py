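"""Exception hierarchy.

Each failure class maps to a distinct CLI exit code (see :mod:`glycopmf.cli`).
"""


class GlycopmfError(Exception):
    """Base class for all package errors."""


class LabelError(GlycopmfError):
    """An atom label could not be resolved against a frame."""


class GeometryError(GlycopmfError):
    """Degenerate geometry (collinear ring, underdetermined superposition, ...)."""


class ConnectivityError(GlycopmfError):
    """The umbrella-window histograms leave a gap along the reaction coordinate."""


class ConvergenceError(GlycopmfError):
    """WHAM self-consistent iteration did not converge within ``max_iter``."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class StabilityError(GlycopmfError):
    """Langevin integration parameters violate the stability bound."""


class ConfigError(GlycopmfError):
    """Run configuration failed schema validation."""


class InputError(GlycopmfError):
    """A required input file is missing or malformed."""
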