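"""Exception hierarchy shared across the pipeline."""


class IsojumpError(Exception):
    """Base class for all package errors."""


class StructureError(IsojumpError):
    """Inconsistent structural definition (sequence/layout mismatch, bad atoms)."""


class ConfigurationError(IsojumpError):
    """Invalid model configuration (unknown residue override, bad parameter)."""


class GeometryError(IsojumpError):
    """Geometrically impossible input, e.g. overlapping transition dipoles."""


class NumericalContractError(IsojumpError):
    """An input violates a numerical contract (e.g. non-symmetric Hamiltonian)."""


class RangeError(IsojumpError):
    """A window, index or grid falls outside the supported range."""


class CalibrationError(IsojumpError):
    """Site-energy or temperature calibration failed."""


class NoTransitionError(IsojumpError):
    """A melt series shows no interior folding transition."""


class WindowError(IsojumpError):
    """A fitting window is too short or outside the data support."""


class FitError(IsojumpError):
    """Nonlinear least squares did not converge."""


class FixtureError(IsojumpError):
    """Request for a variant/band not present in the fixture registry."""
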