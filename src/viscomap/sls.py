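"""Standard-linear-solid (Zener) closed forms.

The material is an isotropic linear viscoelastic solid whose *deviatoric*
response relaxes through a single Prony branch while the volumetric response
stays elastic.  Two equivalent parameterisations are used:

* :class:`MaterialSpec` — the forward-model inputs (E, nu, g, tauR), where E
  and nu are the **long-term** elastic constants and the dimensionless
  relaxation modulus is ``gR(t) = 1 - g (1 - exp(-t/tauR))`` applied to the
  instantaneous shear modulus ``G0 = G_inf / (1 - g)``.
* :class:`SLSParameters` — the Maxwell-form standard linear solid (spring E1
  in parallel with a spring-E2/dashpot-eta Maxwell arm) recovered by fitting
  the uniaxial creep law.

With the long-term reading of (E, nu) the textbook identities ``E = E1``,
``g = E2/(E1+E2)`` and ``tauR = eta/E2`` hold exactly for a homogeneous
uniaxial stress state, which is what makes the full-surface-load /
bottom-roller configuration the reference case of the accuracy study.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .curves import CreepCurve
from .exceptions import DomainError

__all__ = [
    "MaterialSpec",
    "SLSParameters",
    "MaterialProperties",
    "sls_from_material",
    "material_from_fit",
    "creep_strain",
    "relaxation_modulus",
    "dimensionless_relaxation",
    "analytic_uniaxial_response",
    "analytic_confined_response",
]


@dataclass(frozen=True)
class MaterialSpec:
    """Forward-model material inputs.

    E : long-term Young's modulus [Pa]
    nu : Poisson's ratio (long-term), in (0, 0.5)
    g : Prony weight of the single deviatoric branch, in (0, 1)
    tau_R : relaxation time constant [s]
    """

    E: float
    nu: float
    g: float
    tau_R: float

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise DomainError(f"E must be positive, got {self.E}")
        if not 0 < self.nu < 0.5:
            raise DomainError(f"nu must lie in (0, 0.5), got {self.nu}")
        if not 0 < self.g < 1:
            raise DomainError(f"g must lie in (0, 1), got {self.g}")
        if not self.tau_R > 0:
            raise DomainError(f"tau_R must be positive, got {self.tau_R}")

    @property
    def shear_modulus_longterm(self) -> float:
        """G_inf = E / (2 (1 + nu)) [Pa]."""
        return self.E / (2.0 * (1.0 + self.nu))

    @property
    def shear_modulus_instant(self) -> float:
        """G0 = G_inf / (1 - g) [Pa]; the Prony branch relaxes G0 -> G_inf."""
        return self.shear_modulus_longterm / (1.0 - self.g)

    @property
    def bulk_modulus(self) -> float:
        """K = E / (3 (1 - 2 nu)) [Pa]; purely elastic (no volumetric relaxation)."""
        return self.E / (3.0 * (1.0 - 2.0 * self.nu))


@dataclass(frozen=True)
class SLSParameters:
    """Maxwell-form standard linear solid: E1 || (E2 -- eta).

    The derived quantities are exposed as accessors rather than stored, so
    the internal identities (tau_C = tau_R / (1 - g)) cannot be violated.
    """

    E1: float
    E2: float
    eta: float

    def __post_init__(self) -> None:
        for name in ("E1", "E2", "eta"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be positive, got {getattr(self, name)}")

    @property
    def g(self) -> float:
        """Prony weight E2 / (E1 + E2), in (0, 1)."""
        return self.E2 / (self.E1 + self.E2)

    @property
    def tau_R(self) -> float:
        """Relaxation time constant eta / E2 [s]."""
        return self.eta / self.E2

    @property
    def tau_C(self) -> float:
        """Creep (retardation) time constant eta (E1 + E2) / (E1 E2) [s]."""
        return self.eta * (self.E1 + self.E2) / (self.E1 * self.E2)

    @property
    def E_instant(self) -> float:
        """Instantaneous modulus E1 + E2 [Pa]."""
        return self.E1 + self.E2


class MaterialProperties(NamedTuple):
    """The (E, g, tau_R) triple reported by the imaging method."""

    E: float
    g: float
    tau_R: float


def sls_from_material(m: MaterialSpec) -> SLSParameters:
    """Convert forward-model inputs to the equivalent Maxwell-form solid.

    E1 = E, E2 = E g / (1 - g), eta = tau_R * E2.
    """
    E2 = m.E * m.g / (1.0 - m.g)
    return SLSParameters(E1=m.E, E2=E2, eta=m.tau_R * E2)


def material_from_fit(p: SLSParameters) -> MaterialProperties:
    """Back-convert fitted Maxwell-form parameters to (E, g, tau_R)."""
    return MaterialProperties(E=p.E1, g=p.g, tau_R=p.tau_R)


def creep_strain(p: SLSParameters, sigma0: float, t: np.ndarray | float) -> np.ndarray | float:
    """SLS creep strain under a step stress of magnitude sigma0 applied at t=0.

    eps(t) = sigma0/E1 * (1 - E2/(E1+E2) * exp(-t/tau_C)).
    Compression-positive: sigma0 > 0 yields positive, increasing strain.
    """
    if not sigma0 > 0:
        raise DomainError("sigma0 must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("t must be non-negative")
    out = sigma0 / p.E1 * (1.0 - p.g * np.exp(-t / p.tau_C))
    return out if out.ndim else float(out)


def relaxation_modulus(p: SLSParameters, t: np.ndarray | float) -> np.ndarray | float:
    """Stress-relaxation modulus E(t) = E1 + E2 exp(-t/tau_R) [Pa]."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("t must be non-negative")
    out = p.E1 + p.E2 * np.exp(-t / p.tau_R)
    return out if out.ndim else float(out)


def dimensionless_relaxation(g: float, tau_R: float, t: np.ndarray | float) -> np.ndarray | float:
    """One-branch dimensionless relaxation modulus gR(t) = 1 - g (1 - exp(-t/tauR)).

    Strictly decreasing from 1 at t=0 towards 1-g.
    """
    if not 0 < g < 1:
        raise DomainError(f"g must lie in (0, 1), got {g}")
    if not tau_R > 0:
        raise DomainError(f"tau_R must be positive, got {tau_R}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("t must be non-negative")
    out = 1.0 - g * (1.0 - np.exp(-t / tau_R))
    return out if out.ndim else float(out)


def _ramp_factor(tau_c: float, ramp_time: float) -> float:
    """Amplitude factor on the creep exponential for a linear stress ramp.

    For a stress ramped linearly over ``ramp_time`` and then held, Boltzmann
    superposition turns the step-load exponential ``exp(-t/tau_c)`` (t
    measured from the end of the ramp) into ``kappa * exp(-t/tau_c)`` with
    kappa = (tau_c/t_r)(1 - exp(-t_r/tau_c)) <= 1.  ramp_time = 0 recovers
    the ideal step load.
    """
    if ramp_time == 0.0:
        return 1.0
    x = ramp_time / tau_c
    return (1.0 - np.exp(-x)) / x


def _sls_creep_from_relaxation(M_inf: float, M0: float, tau_R: float,
                               sigma0: float, times: np.ndarray,
                               ramp_time: float = 0.0) -> np.ndarray:
    """Creep strain of a single-branch solid with relaxation M(t) = M_inf + (M0-M_inf) e^{-t/tauR}.

    The exact interconversion gives a single-exponential creep compliance
    D(t) = 1/M_inf - (1/M_inf - 1/M0) exp(-t/tau_c) with tau_c = tau_R * M0 / M_inf.
    """
    tau_c = tau_R * M0 / M_inf
    kappa = _ramp_factor(tau_c, ramp_time)
    D = 1.0 / M_inf - (1.0 / M_inf - 1.0 / M0) * kappa * np.exp(-times / tau_c)
    return sigma0 * D


def analytic_uniaxial_response(m: MaterialSpec, sigma0: float,
                               times: np.ndarray,
                               ramp_time: float = 0.0) -> CreepCurve:
    """Exact axial creep strain for a homogeneous *uniaxial-stress* state.

    This is the state realised by a full-surface pressure with the bottom on
    frictionless rollers and a free side.  With elastic bulk K and SLS shear,
    the uniaxial creep compliance is

        D(t) = 1/(9K) + (1/3) [1/G_inf - (1/G_inf - 1/G0) exp(-t/tau_cs)],
        tau_cs = tau_R * G0 / G_inf = tau_R / (1 - g),

    a single exponential, so fitting the uniaxial creep law to it is exact:
    the long-term modulus 1/D(inf) equals E identically (E = 9KG/(3K+G)).

    ``ramp_time > 0`` replaces the ideal step load by a linear ramp of that
    duration ending at t = 0 (see :func:`_ramp_factor`), matching how the
    forward finite-element model applies the pressure.
    """
    if not sigma0 > 0:
        raise DomainError("sigma0 must be positive")
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise DomainError("times must be non-negative")
    K, G_inf, G0 = m.bulk_modulus, m.shear_modulus_longterm, m.shear_modulus_instant
    tau_cs = m.tau_R * G0 / G_inf
    kappa = _ramp_factor(tau_cs, ramp_time)
    D = 1.0 / (9.0 * K) + (1.0 / 3.0) * (
        1.0 / G_inf - (1.0 / G_inf - 1.0 / G0) * kappa * np.exp(-times / tau_cs)
    )
    return CreepCurve(times=times, eps_zz=sigma0 * D, sigma0=sigma0)


def analytic_confined_response(m: MaterialSpec, sigma0: float,
                               times: np.ndarray,
                               ramp_time: float = 0.0) -> CreepCurve:
    """Exact axial creep strain under *confined* compression (zero lateral strain).

    The governing modulus is the P-wave-type modulus M(t) = K + (4/3) G(t),
    which relaxes with the shear time constant tau_R.  Fitting the uniaxial
    creep law to this curve therefore returns E1 = M_inf (far above E) and a
    small apparent g = 1 - M_inf/M0, but the back-converted tau_R is exact —
    the mechanism behind the confined-boundary row of the accuracy table.
    """
    if not sigma0 > 0:
        raise DomainError("sigma0 must be positive")
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise DomainError("times must be non-negative")
    K, G_inf, G0 = m.bulk_modulus, m.shear_modulus_longterm, m.shear_modulus_instant
    M_inf = K + 4.0 * G_inf / 3.0
    M0 = K + 4.0 * G0 / 3.0
    eps = _sls_creep_from_relaxation(M_inf, M0, m.tau_R, sigma0, times, ramp_time)
    return CreepCurve(times=times, eps_zz=eps, sigma0=sigma0)
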