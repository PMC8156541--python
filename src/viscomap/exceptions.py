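"""Exception hierarchy shared across the package."""


class ViscomapError(Exception):
    """Base class for all package-specific errors."""


class DomainError(ViscomapError, ValueError):
    """A physical/mathematical input lies outside its admissible domain."""


class MeshConfigError(ViscomapError, ValueError):
    """Geometry is incompatible with the requested element size."""


class SolverError(ViscomapError, RuntimeError):
    """The quasi-static solve failed (singular system, divergence)."""


class DegenerateCurveError(ViscomapError, ValueError):
    """A creep curve carries no usable relaxation signal."""


class StructuralError(ViscomapError, ValueError):
    """A collection of results does not form the required structure."""
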