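"""Synthetic creep-curve generator with known ground truth.

Curves are drawn directly from the standard-linear-solid creep law, so the
inversion and mapping stages can be exercised (and their error statistics
calibrated) without the finite-element solver.  The perturbation model is
multiplicative Gaussian noise, eps * (1 + sigma_noise * z): scale-free
across the full strain range of a creep curve, seeded and reproducible.
It does not emulate ultrasound speckle or displacement-estimation physics.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .curves import CreepCurve
from .exceptions import DomainError
from .sls import MaterialSpec, SLSParameters, creep_strain, sls_from_material

__all__ = ["SyntheticDataset", "Pattern", "generate_curves", "heterogeneity_pattern"]


class Pattern(str, Enum):
    UNIFORM = "uniform"
    VERTICAL_GRADIENT = "vertical_gradient"
    CHECKER = "checker"


@dataclass(frozen=True)
class SyntheticDataset:
    """A seeded set of creep curves plus the parameter grid that generated them."""

    curves: list[CreepCurve]
    truth: np.ndarray            # (ni, nj) object array of SLSParameters
    noise: float
    seed: int | None


def _as_sls(theta) -> SLSParameters:
    if isinstance(theta, SLSParameters):
        return theta
    if isinstance(theta, MaterialSpec):
        return sls_from_material(theta)
    raise DomainError(f"expected MaterialSpec or SLSParameters, got {type(theta).__name__}")


def generate_curves(grid, sigma0: float, times: np.ndarray,
                    noise: float = 0.0, seed: int | None = None) -> SyntheticDataset:
    """Generate one creep curve per grid cell.

    grid : 2-D array-like of MaterialSpec or SLSParameters, indexed [i, j].
    noise : multiplicative Gaussian noise level (0 gives exact curves).
    Identical seeds reproduce identical datasets bit-for-bit.
    """
    if noise < 0:
        raise DomainError("noise must be non-negative")
    times = np.asarray(times, dtype=float)
    if times[0] != 0.0 or np.any(np.diff(times) <= 0):
        raise DomainError("times must be strictly increasing from 0")
    grid = np.asarray(grid, dtype=object)
    if grid.ndim == 1:
        grid = grid[:, None]
    rng = np.random.default_rng(seed)
    truth = np.empty(grid.shape, dtype=object)
    curves: list[CreepCurve] = []
    ni, nj = grid.shape
    for i in range(ni):
        for j in range(nj):
            try:
                p = _as_sls(grid[i, j])
            except DomainError as exc:
                raise DomainError(f"invalid parameters at grid position ({i}, {j}): {exc}") from exc
            truth[i, j] = p
            eps = np.asarray(creep_strain(p, sigma0, times), dtype=float)
            if noise > 0:
                eps = eps * (1.0 + noise * rng.standard_normal(times.shape))
            curves.append(CreepCurve(times=times, eps_zz=eps, sigma0=sigma0,
                                     element=(i, j)))
    return SyntheticDataset(curves=curves, truth=truth, noise=noise, seed=seed)


def heterogeneity_pattern(base: MaterialSpec, pattern: Pattern | str,
                          amplitude: float, shape: tuple[int, int] = (10, 10)) -> np.ndarray:
    """Parameter grids for map-rendering tests (the study itself is homogeneous).

    uniform: constant grid equal to ``base``.
    vertical_gradient: E scaled linearly with depth, base*(1-amplitude) in
      the top row to base*(1+amplitude) in the bottom row (rows index depth
      from the top, j=0 top).
    checker: E scaled by (1 +/- amplitude) in alternating blocks.
    Returned grid is indexed [j, i] = (row from top, column), dtype=object.
    """
    pattern = Pattern(pattern)
    if not 0 <= amplitude < 0.5:
        raise DomainError(f"amplitude must lie in [0, 0.5), got {amplitude}")
    nrow, ncol = shape
    grid = np.empty((nrow, ncol), dtype=object)
    for j in range(nrow):
        for i in range(ncol):
            if pattern is Pattern.UNIFORM:
                scale = 1.0
            elif pattern is Pattern.VERTICAL_GRADIENT:
                frac = j / (nrow - 1) if nrow > 1 else 0.0
                scale = (1.0 - amplitude) + 2.0 * amplitude * frac
            else:
                scale = 1.0 + amplitude * (1 if (i + j) % 2 == 0 else -1)
            grid[j, i] = MaterialSpec(E=base.E * scale, nu=base.nu,
                                      g=base.g, tau_R=base.tau_R)
    return grid
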