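"""Per-element inversion of the standard-linear-solid creep law.

Every imaging-region element's hold-phase axial strain series is fitted with
the step-load creep law

    eps(t) = sigma0/E1 * (1 - E2/(E1+E2) * exp(-t/tau_C))

by bounded nonlinear least squares over (E1, E2, tau_C), with sigma0 fixed at
the *applied* surface pressure.  That nominal-stress assumption is the
modelling idealisation whose breakdown under non-ideal loading/boundary
conditions this package quantifies, so it is deliberately not corrected.

When a curve records a finite pressure ramp (``CreepCurve.ramp_time > 0``),
the fitted model carries the exact Boltzmann-superposition amplitude factor
kappa(tau_C) = (1 - exp(-t_r/tau_C)) / (t_r/tau_C) on the exponential term,
so the recovered (E1, E2, tau_C) are those of the ideal step-load experiment
the creep law describes; for single-exponential strain histories the
compensation is exact.  With ramp_time = 0 the model is the plain step law.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .curves import CreepCurve
from .exceptions import DegenerateCurveError, StructuralError
from .sls import SLSParameters

__all__ = ["FitResult", "FieldFit", "initial_guess", "fit_creep_curve", "fit_field"]


@dataclass(frozen=True)
class FitResult:
    """Outcome of fitting one creep curve."""

    params: SLSParameters | None
    converged: bool
    residual_norm: float
    iterations: int
    element: tuple[int, int] | None = None


def initial_guess(c: CreepCurve) -> SLSParameters:
    """Moment-style starting point from the curve's endpoints and 63.2% rise time.

    E1 from the plateau strain, g from the instantaneous-to-plateau strain
    ratio (clipped to [0.01, 0.99]), tau_C from the time at which the strain
    crosses ``eps0 + (1 - 1/e)(eps_end - eps0)`` by linear interpolation.
    """
    eps0, eps_end = c.eps_zz[0], c.eps_zz[-1]
    if eps_end <= eps0 or eps_end <= 0:
        raise DegenerateCurveError(
            "curve shows no creep (eps(t_end) <= eps(0)); cannot seed a fit")
    E1 = c.sigma0 / eps_end
    g = float(np.clip(1.0 - eps0 / eps_end, 0.01, 0.99))
    E2 = E1 * g / (1.0 - g)
    target = eps0 + (1.0 - np.e ** -1.0) * (eps_end - eps0)
    k = int(np.searchsorted(c.eps_zz >= target, True))
    if k == 0:
        tau_C = c.times[1] / 2.0
    else:
        e0, e1 = c.eps_zz[k - 1], c.eps_zz[k]
        frac = (target - e0) / (e1 - e0) if e1 > e0 else 0.5
        tau_C = c.times[k - 1] + frac * (c.times[k] - c.times[k - 1])
    tau_C = max(tau_C, c.times[1] / 10.0)
    eta = tau_C * E1 * E2 / (E1 + E2)
    return SLSParameters(E1=E1, E2=E2, eta=eta)


def _model_and_jac(theta: np.ndarray, t: np.ndarray, sigma0: float, t_ramp: float):
    E1, E2, tau = theta
    S = E1 + E2
    g = E2 / S
    ex = np.exp(-t / tau)
    if t_ramp > 0.0:
        a = t_ramp / tau
        ea = np.exp(-a)
        kappa = (1.0 - ea) / a
        dkappa = (1.0 - ea * (a + 1.0)) / (a * tau)   # d kappa / d tau
    else:
        kappa, dkappa = 1.0, 0.0
    kex = kappa * ex
    eps = sigma0 / E1 * (1.0 - g * kex)
    d_E1 = -sigma0 / E1**2 * (1.0 - g * kex) + sigma0 / E1 * (E2 / S**2) * kex
    d_E2 = -sigma0 / E1 * (E1 / S**2) * kex
    d_tau = -sigma0 / E1 * g * (dkappa * ex + kappa * ex * t / tau**2)
    return eps, np.column_stack([d_E1, d_E2, d_tau])


def fit_creep_curve(c: CreepCurve) -> FitResult:
    """Bounded trust-region least squares on (E1, E2, tau_C), seeded by initial_guess.

    Unweighted residuals.  eta is recovered from the fitted creep time
    constant via eta = tau_C * E1 E2 / (E1 + E2).  A degenerate curve or an
    optimizer failure yields ``converged=False`` (downstream maps treat that
    as an infinite error).
    """
    try:
        p0 = initial_guess(c)
    except DegenerateCurveError:
        return FitResult(params=None, converged=False, residual_norm=np.inf,
                         iterations=0, element=c.element)
    x0 = np.array([p0.E1, p0.E2, p0.tau_C])
    t, eps, sigma0 = c.times, c.eps_zz, c.sigma0
    t_ramp = c.ramp_time

    def resid(theta):
        return _model_and_jac(theta, t, sigma0, t_ramp)[0] - eps

    def jac(theta):
        return _model_and_jac(theta, t, sigma0, t_ramp)[1]

    tiny = 1e-12
    try:
        sol = least_squares(resid, x0, jac=jac, bounds=(tiny, np.inf),
                            method="trf", x_scale=np.abs(x0),
                            xtol=1e-12, ftol=1e-14, gtol=1e-12, max_nfev=200)
    except Exception:
        return FitResult(params=None, converged=False, residual_norm=np.inf,
                         iterations=0, element=c.element)
    ok = bool(sol.success) and np.all(np.isfinite(sol.x)) and np.all(sol.x > 0)
    if not ok:
        return FitResult(params=None, converged=False, residual_norm=np.inf,
                         iterations=int(sol.nfev), element=c.element)
    E1, E2, tau_C = sol.x
    eta = tau_C * E1 * E2 / (E1 + E2)
    return FitResult(params=SLSParameters(E1=E1, E2=E2, eta=eta),
                     converged=True,
                     residual_norm=float(np.linalg.norm(sol.fun)),
                     iterations=int(sol.nfev), element=c.element)


@dataclass
class FieldFit:
    """Per-element fitted parameters on a rectangular imaging grid.

    Grids are indexed [i, j] (radial, vertical-from-bottom) and hold NaN
    where the fit failed; ``converged`` is the corresponding boolean mask.
    """

    E1: np.ndarray
    E2: np.ndarray
    eta: np.ndarray
    converged: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.E1.shape

    @property
    def E(self) -> np.ndarray:
        return self.E1

    @property
    def g(self) -> np.ndarray:
        return self.E2 / (self.E1 + self.E2)

    @property
    def tau_R(self) -> np.ndarray:
        return self.eta / self.E2


def fit_field(curves: list[CreepCurve]) -> FieldFit:
    """Fit every curve independently and arrange results on the imaging grid.

    The curves must carry element indices covering a full rectangle.  Fits
    are independent, so the result does not depend on the input order.
    """
    if not curves:
        raise StructuralError("no curves supplied")
    idx = np.array([c.element for c in curves])
    if idx.ndim != 2 or any(c.element is None for c in curves):
        raise StructuralError("every curve needs (i, j) element indices")
    i0, j0 = idx.min(axis=0)
    ni, nj = idx.max(axis=0) - (i0, j0) + 1
    expected = ni * nj
    if len(curves) != expected or len({tuple(e) for e in idx}) != expected:
        raise StructuralError(
            f"curves do not tile a full {ni} x {nj} rectangle")
    E1 = np.full((ni, nj), np.nan)
    E2 = np.full((ni, nj), np.nan)
    eta = np.full((ni, nj), np.nan)
    conv = np.zeros((ni, nj), dtype=bool)
    for c in curves:
        res = fit_creep_curve(c)
        i, j = c.element[0] - i0, c.element[1] - j0
        conv[i, j] = res.converged
        if res.converged:
            E1[i, j] = res.params.E1
            E2[i, j] = res.params.E2
            eta[i, j] = res.params.eta
    return FieldFit(E1=E1, E2=E2, eta=eta, converged=conv)
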