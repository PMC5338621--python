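"""Exception hierarchy shared across the package."""


class CemfwdError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CemfwdError, ValueError):
    """Invalid argument values (non-increasing radii, nonpositive impedance, ...)."""


class MeshError(CemfwdError):
    """Problems with mesh topology or geometry."""


class LabelDataError(MeshError):
    """Mesh file lacks the integer compartment-label cell-data field."""


class UnsupportedCellError(MeshError):
    """Mesh file contains cells other than linear tetrahedra."""


class ResolutionError(MeshError):
    """Requested edge length too coarse to resolve the thinnest shell."""


class AssemblyError(CemfwdError):
    """Finite-element assembly failure (e.g. degenerate tetrahedron)."""


class ElectrodeError(CemfwdError):
    """Electrode cap construction problems."""


class EmptyElectrodeError(ElectrodeError):
    """An electrode patch captured no boundary triangles."""


class OverlapError(ElectrodeError):
    """Two electrode patches claim the same boundary triangle."""


class GroundingError(CemfwdError):
    """No boundary node available outside all electrode patches."""


class SolverError(CemfwdError):
    """Linear solver failed to reach the requested residual tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class UnsupportedModelError(CemfwdError):
    """Operation applied to the wrong electrode model (e.g. PEM where CEM needed)."""


class ConfigurationError(CemfwdError):
    """Inconsistent or incomplete experiment/source configuration."""


class SamplingError(CemfwdError):
    """Not enough admissible dipoles in a requested eccentricity band."""


class UndefinedMeasureError(CemfwdError, ValueError):
    """Comparison measure undefined for the given input (zero vector/moment)."""


class DegenerateEstimateError(CemfwdError):
    """Inverse estimate has zero total amplitude; no dipole summary exists."""
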