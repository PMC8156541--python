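"""Property maps, error maps and the region-accuracy statistic.

The imaging region is the half cross-section under the transducer (radius
25 mm, full depth by default).  Each fitted property is rendered as a 2-D
map indexed [i, j] = (radial column, vertical row from the bottom); the map
of the axisymmetric half is mirrored about the axis to produce the full
cross-section image.  The error map is the element-wise relative deviation
|fit - set| / set, and the accuracy percentage counts the elements whose
error is strictly below the tolerance (10% by default).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import DomainError, StructuralError
from .fem import StrainFieldHistory
from .fitting import FieldFit

__all__ = [
    "PropertyMap",
    "ErrorMap",
    "property_maps_from_fit",
    "error_map",
    "accuracy_percentage",
    "mirror_full",
    "horizontal_strain_map",
]

PROPERTY_IDS = ("E", "tauR", "g")


@dataclass(frozen=True)
class PropertyMap:
    """2-D map of one fitted property.

    values[i, j]: i indexes radial columns (axis outwards for a half map),
    j indexes rows from the bottom.  Failed fits are NaN.
    """

    property_id: str
    values: np.ndarray
    h: float
    full: bool = False

    def __post_init__(self) -> None:
        if self.property_id not in PROPERTY_IDS:
            raise DomainError(f"unknown property id {self.property_id!r}")
        if self.values.ndim != 2 or self.values.size == 0:
            raise StructuralError("map values must be a non-empty 2-D grid")


@dataclass(frozen=True)
class ErrorMap:
    """Element-wise relative error grid (failed fits are +inf)."""

    property_id: str
    errors: np.ndarray
    theoretical: float

    def __post_init__(self) -> None:
        if np.any(self.errors < 0):
            raise DomainError("relative errors cannot be negative")


def property_maps_from_fit(fit: FieldFit, h: float) -> dict[str, PropertyMap]:
    """The (E, tauR, g) half maps reported by the imaging method."""
    grids = {"E": fit.E, "tauR": fit.tau_R, "g": fit.g}
    return {pid: PropertyMap(property_id=pid, values=np.array(grid), h=h)
            for pid, grid in grids.items()}


def error_map(pmap: PropertyMap, theoretical: float) -> ErrorMap:
    """Relative error |simulation - theoretical| / theoretical per element."""
    if not theoretical > 0:
        raise DomainError("theoretical value must be positive")
    err = np.abs(pmap.values - theoretical) / theoretical
    err = np.where(np.isnan(err), np.inf, err)
    return ErrorMap(property_id=pmap.property_id, errors=err, theoretical=theoretical)


def accuracy_percentage(err: ErrorMap, tol: float = 0.10) -> float:
    """Percent of map elements with error strictly below ``tol``.

    Counting is per element of the supplied map; mirroring doubles both the
    accurate count and the total, so the percentage is mirror-invariant.
    """
    if err.errors.size == 0:
        raise StructuralError("empty error map")
    return 100.0 * float(np.count_nonzero(err.errors < tol)) / err.errors.size


def mirror_full(pmap: PropertyMap) -> PropertyMap:
    """Reflect a half map about the axis and concatenate into the full image."""
    if pmap.full:
        raise DomainError("map is already a full (mirrored) map")
    full_values = np.concatenate([pmap.values[::-1, :], pmap.values], axis=0)
    return replace(pmap, values=full_values, full=True)


def horizontal_strain_map(hist: StrainFieldHistory, t: float,
                          imaging_radius: float | None = None) -> np.ndarray:
    """Full-width radial (horizontal) strain image at the stored time nearest t.

    Returns eps_rr at element centroids over the imaging region, mirrored to
    the full cross-section with the sign flipped in the reflected half so
    that the image reads as Cartesian horizontal strain (lateral motion is
    left-right antisymmetric about the axis).  Shape (2*nr_img, nz).
    """
    k = hist.index_at(t)
    mesh = hist.mesh
    if imaging_radius is None:
        imaging_radius = mesh.radius / 2.0
    if imaging_radius > mesh.radius + 1e-12:
        raise DomainError("imaging_radius exceeds the mesh radius")
    ncol = int(np.sum((np.arange(mesh.nr) + 0.5) * mesh.h <= imaging_radius))
    half = hist.eps_rr[k].reshape(mesh.nz, mesh.nr).T[:ncol, :]   # [i, j]
    return np.concatenate([-half[::-1, :], half], axis=0)
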