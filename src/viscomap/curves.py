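"""Creep-curve container shared by the forward model, the generator and the fitter."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DomainError


@dataclass(frozen=True)
class CreepCurve:
    """Hold-phase axial strain history of one element.

    Sign convention is compression-positive: under a downward surface
    pressure ``eps_zz`` is positive and non-decreasing.  ``times`` start at 0
    at the instant the applied pressure first reaches its plateau, and
    ``sigma0`` is the *applied* surface pressure magnitude (Pa) — the creep
    law is always inverted against that nominal stress, whether or not it
    equals the element's true axial stress.

    ``ramp_time`` records the duration of the linear pressure ramp that
    preceded the hold (0 for an ideal step load); the fitter uses it to
    compensate the ramp exactly, so fitted parameters always refer to the
    ideal step-load creep law.

    element: grid indices (i radial, j vertical) or None for free-standing
    curves.
    """

    times: np.ndarray
    eps_zz: np.ndarray
    sigma0: float
    element: tuple[int, int] | None = None
    ramp_time: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.eps_zz, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "eps_zz", e)
        if t.ndim != 1 or e.shape != t.shape:
            raise DomainError("times and eps_zz must be 1-D arrays of equal length")
        if t.size < 4:
            raise DomainError("a creep curve needs >= 4 samples to identify 3 parameters")
        if t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise DomainError("times must be strictly increasing starting at 0")
        if not np.all(np.isfinite(e)):
            raise DomainError("strains must be finite")
        if not self.sigma0 > 0:
            raise DomainError("sigma0 must be positive (compression-positive convention)")
        if self.ramp_time < 0:
            raise DomainError("ramp_time must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(self.times.size)
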