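"""Axisymmetric quasi-static finite-element solver for ramp-and-hold creep.

A cylindrical sample (radius x thickness cross-section in the (r, z) plane)
of near-incompressible linear viscoelastic material is compressed by a
uniform surface pressure that ramps linearly to its plateau and is then held
constant.  The solver advances quasi-static equilibrium in time with:

* 4-node axisymmetric quadrilaterals with 2x2 Gauss quadrature;
* B-bar element technology — the volumetric part of the strain-displacement
  operator (including the hoop term u_r/r) is replaced by its element-volume
  average, which removes volumetric locking at nu = 0.495;
* elastic volumetric stress p = K tr(eps); deviatoric stress through the
  one-branch Prony hereditary integral s(t) = 2 ∫ G(t-t') de(t'), with
  G(t) = G0 [1 - g (1 - e^{-t/tauR})], integrated by the standard recursive
  exponential internal-variable update (strain assumed linear in each step);
* a direct sparse factorisation reused across every step of a constant-dt
  phase (the effective step modulus depends only on dt).

Strains are reported at element centroids with the compression-positive sign
convention (all four components are negated physical strains, so eps_zz > 0
under the downward pressure).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .curves import CreepCurve
from .exceptions import DomainError, MeshConfigError, SolverError
from .sls import MaterialSpec

__all__ = [
    "AxisymmetricMesh",
    "Coverage",
    "BottomFix",
    "SideFix",
    "LoadingProtocol",
    "BoundaryConditionSpec",
    "StrainFieldHistory",
    "build_mesh",
    "run_forward",
    "extract_creep_curves",
]

#: Voigt component order used throughout: (eps_rr, eps_zz, eps_tt, gamma_rz).
VOIGT_COMPONENTS = ("eps_rr", "eps_zz", "eps_tt", "gamma_rz")

_M_VOL = np.array([1.0, 1.0, 1.0, 0.0])
# deviatoric projector mapping Voigt strain (engineering shear) to
# "stress-ready" deviatoric strain: s = 2 G * (J @ eps)
_J_DEV = np.array(
    [
        [2 / 3, -1 / 3, -1 / 3, 0.0],
        [-1 / 3, 2 / 3, -1 / 3, 0.0],
        [-1 / 3, -1 / 3, 2 / 3, 0.0],
        [0.0, 0.0, 0.0, 0.5],
    ]
)


# ---------------------------------------------------------------------------
# mesh
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AxisymmetricMesh:
    """Structured grid of square 4-node quads on [0, radius] x [0, thickness].

    Node (ir, iz) has id ``iz * (nr + 1) + ir``; element (i, j) has id
    ``j * nr + i`` with counter-clockwise connectivity and centroid at
    ((i + 1/2) h, (j + 1/2) h), measured from the axis and the bottom.
    """

    radius: float
    thickness: float
    h: float
    nr: int
    nz: int
    coords: np.ndarray  # (n_nodes, 2): columns r, z
    conn: np.ndarray    # (n_elem, 4) CCW node ids

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    @property
    def n_elements(self) -> int:
        return self.conn.shape[0]

    @property
    def centroids(self) -> np.ndarray:
        """(n_elem, 2) element centroid coordinates."""
        return self.coords[self.conn].mean(axis=1)

    def element_grid_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(i, j) grid indices for every element id."""
        ids = np.arange(self.n_elements)
        return ids % self.nr, ids // self.nr


def _divisions(length: float, h: float, name: str) -> int:
    n = length / h
    n_round = round(n)
    if n_round < 1 or abs(n - n_round) > 1e-9 * max(1.0, n):
        raise MeshConfigError(f"{name} ({length} m) is not a positive integer multiple of h ({h} m)")
    return int(n_round)


def build_mesh(radius: float, thickness: float, h: float) -> AxisymmetricMesh:
    """Build the structured square-element mesh (default 100 x 100 at h = 0.5 mm)."""
    if h <= 0:
        raise MeshConfigError(f"element size must be positive, got {h}")
    nr = _divisions(radius, h, "radius")
    nz = _divisions(thickness, h, "thickness")
    r = np.linspace(0.0, radius, nr + 1)
    z = np.linspace(0.0, thickness, nz + 1)
    R, Z = np.meshgrid(r, z)            # row = iz, col = ir
    coords = np.column_stack([R.ravel(), Z.ravel()])
    i, j = np.meshgrid(np.arange(nr), np.arange(nz))
    i, j = i.ravel(), j.ravel()
    n00 = j * (nr + 1) + i
    conn = np.column_stack([n00, n00 + 1, n00 + nr + 2, n00 + nr + 1])
    return AxisymmetricMesh(radius=radius, thickness=thickness, h=h,
                            nr=nr, nz=nz, coords=coords, conn=conn)


# ---------------------------------------------------------------------------
# loading / boundary conditions
# ---------------------------------------------------------------------------

class Coverage(str, Enum):
    FULL_TOP = "full_top"
    HALF_TOP = "half_top"


class BottomFix(str, Enum):
    VERTICAL_ONLY = "vertical_only"
    ALL_DIRECTIONS = "all_directions"


class SideFix(str, Enum):
    FREE = "free"
    HORIZONTAL = "horizontal"


@dataclass(frozen=True)
class LoadingProtocol:
    """Ramp-and-hold surface pressure.

    p_max ramps linearly from 0 over ``ramp_time`` and is then held constant
    for ``hold_time``.  ``coverage`` selects whether the pressure acts on the
    entire top surface or on the inner half of the top edge (0 <= r <= R/2,
    which matches the imaging region).  ``extent`` overrides the
    coverage-derived radial extent explicitly.
    """

    p_max: float = 1000.0
    ramp_time: float = 1.0 / 6.0
    hold_time: float = 150.0
    coverage: Coverage = Coverage.FULL_TOP
    extent: float | None = None

    def __post_init__(self) -> None:
        if self.p_max < 0:
            raise DomainError(f"p_max must be non-negative, got {self.p_max}")
        if self.ramp_time <= 0 or self.hold_time <= 0:
            raise DomainError("ramp_time and hold_time must be positive")
        if self.extent is not None and self.extent <= 0:
            raise DomainError("explicit loaded extent must be positive")

    def loaded_extent(self, radius: float) -> float:
        """Radial extent of the pressurised top edge [m]."""
        if self.extent is not None:
            return self.extent
        return radius if self.coverage is Coverage.FULL_TOP else radius / 2.0


@dataclass(frozen=True)
class BoundaryConditionSpec:
    """Fixation of the sample.  The symmetry axis r=0 always has u_r = 0."""

    bottom_fix: BottomFix = BottomFix.VERTICAL_ONLY
    side_fix: SideFix = SideFix.FREE


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------

@dataclass
class StrainFieldHistory:
    """Centroid strain histories from a forward solve.

    strains has shape (n_times, n_elements, 4) in the order
    (eps_rr, eps_zz, eps_tt, gamma_rz), compression-positive (negated
    physical strains).  ``reaction_residuals`` is the normalised equilibrium
    check |sum of vertical reactions - applied load| / applied load per
    recorded time (0 where the load is zero).
    """

    times: np.ndarray
    strains: np.ndarray
    pressure: np.ndarray
    mesh: AxisymmetricMesh
    material: MaterialSpec
    load: LoadingProtocol
    bc: BoundaryConditionSpec
    reaction_residuals: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def eps_rr(self) -> np.ndarray:
        return self.strains[:, :, 0]

    @property
    def eps_zz(self) -> np.ndarray:
        return self.strains[:, :, 1]

    def index_at(self, t: float) -> int:
        """Index of the stored time nearest to t (t must lie within the history)."""
        if t < self.times[0] - 1e-12 or t > self.times[-1] + 1e-12:
            raise DomainError(f"t={t} outside stored history [{self.times[0]}, {self.times[-1]}]")
        return int(np.argmin(np.abs(self.times - t)))


# ---------------------------------------------------------------------------
# element matrices
# ---------------------------------------------------------------------------

def _element_operators(mesh: AxisymmetricMesh):
    """Precompute B-bar operators and integration weights for all elements.

    Returns (Bbar_gp (nel,4,4,8), w_gp (nel,4), Bbar_c (nel,4,8), dofmat (nel,8)).
    Weights include the 2*pi*r axisymmetric measure.
    """
    h = mesh.h
    gp = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    # Gauss points (xi, eta) and centroid appended for centroid operator
    pts = [(xi, eta) for eta in gp for xi in gp]

    conn = mesh.conn
    nel = mesh.n_elements
    xe = mesh.coords[conn]                      # (nel, 4, 2)
    r0 = xe[:, :, 0].mean(axis=1)               # centroid r per element
    z0 = xe[:, :, 1].mean(axis=1)

    def shape(xi, eta):
        N = 0.25 * np.array([(1 - xi) * (1 - eta), (1 + xi) * (1 - eta),
                             (1 + xi) * (1 + eta), (1 - xi) * (1 + eta)])
        dN_dxi = 0.25 * np.array([-(1 - eta), (1 - eta), (1 + eta), -(1 + eta)])
        dN_deta = 0.25 * np.array([-(1 - xi), -(1 + xi), (1 + xi), (1 - xi)])
        return N, dN_dxi, dN_deta

    detJ = (h / 2.0) ** 2                       # square elements, axis-aligned

    def B_and_bvol(xi, eta):
        """B (nel,4,8) and volumetric row b (nel,8) at one parent point."""
        N, dNx, dNe = shape(xi, eta)
        dNdr = dNx * (2.0 / h)                  # (4,)
        dNdz = dNe * (2.0 / h)
        r = r0 + xi * h / 2.0                   # (nel,) radius at the point
        B = np.zeros((nel, 4, 8))
        for a in range(4):
            B[:, 0, 2 * a] = dNdr[a]
            B[:, 1, 2 * a + 1] = dNdz[a]
            B[:, 2, 2 * a] = N[a] / r
            B[:, 3, 2 * a] = dNdz[a]
            B[:, 3, 2 * a + 1] = dNdr[a]
        b = B[:, 0, :] + B[:, 1, :] + B[:, 2, :]
        return B, b, r

    # element-volume-averaged volumetric operator (hoop included, r-weighted)
    b_bar = np.zeros((nel, 8))
    vol = np.zeros(nel)
    B_gp, b_gp, r_gp = [], [], []
    for (xi, eta) in pts:
        B, b, r = B_and_bvol(xi, eta)
        w = 2.0 * np.pi * r * detJ              # unit Gauss weights
        b_bar += b * w[:, None]
        vol += w
        B_gp.append(B)
        b_gp.append(b)
        r_gp.append(r)
    b_bar /= vol[:, None]

    Bbar_gp = np.empty((nel, 4, 4, 8))
    w_gp = np.empty((nel, 4))
    for k in range(4):
        corr = (b_bar - b_gp[k]) / 3.0          # (nel, 8)
        Bbar_gp[:, k] = B_gp[k] + _M_VOL[None, :, None] * corr[:, None, :]
        w_gp[:, k] = 2.0 * np.pi * r_gp[k] * detJ

    # centroid operator with the same B-bar correction
    Bc, bc, _ = B_and_bvol(0.0, 0.0)
    Bbar_c = Bc + _M_VOL[None, :, None] * ((b_bar - bc) / 3.0)[:, None, :]

    dofmat = np.empty((nel, 8), dtype=np.int64)
    dofmat[:, 0::2] = 2 * conn
    dofmat[:, 1::2] = 2 * conn + 1
    return Bbar_gp, w_gp, Bbar_c, dofmat


def _assemble_global(Bbar_gp, w_gp, dofmat, D, n_dof):
    """Assemble the global matrix for the 4x4 constitutive matrix D."""
    nel = Bbar_gp.shape[0]
    Ke = np.zeros((nel, 8, 8))
    for k in range(4):
        Bk = Bbar_gp[:, k]                      # (nel, 4, 8)
        DB = np.einsum("ab,ebj->eaj", D, Bk)
        Ke += w_gp[:, k, None, None] * np.einsum("eai,eaj->eij", Bk, DB)
    rows = np.repeat(dofmat, 8, axis=1).ravel()
    cols = np.tile(dofmat, (1, 8)).ravel()
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n_dof, n_dof))
    return K.tocsc()


def _traction_vector(mesh: AxisymmetricMesh, extent: float) -> np.ndarray:
    """Consistent nodal loads for a unit downward pressure on r <= extent (top edge).

    An extent that ends inside an element edge is handled exactly by
    integrating the edge shape functions over the covered part only, so the
    applied resultant is exactly ``pi * extent**2 * p`` for any extent.
    """
    if extent > mesh.radius + 1e-12:
        raise MeshConfigError(f"loaded extent {extent} m exceeds the mesh radius")
    n_dof = 2 * mesh.n_nodes
    f = np.zeros(n_dof)
    h = mesh.h
    top_row = mesh.nz * (mesh.nr + 1)
    n_full = min(int(np.floor(extent / h + 1e-12)), mesh.nr)
    for i in range(n_full):
        r1, r2 = i * h, (i + 1) * h
        na, nb = top_row + i, top_row + i + 1
        # consistent load: 2*pi * p * integral of N_a r dr over the edge
        f[2 * na + 1] -= 2.0 * np.pi * h * (2.0 * r1 + r2) / 6.0
        f[2 * nb + 1] -= 2.0 * np.pi * h * (r1 + 2.0 * r2) / 6.0
    c = extent - n_full * h
    if c > 1e-12 * h and n_full < mesh.nr:
        r1 = n_full * h
        na, nb = top_row + n_full, top_row + n_full + 1
        moment = (r1 * c**2 / 2.0 + c**3 / 3.0) / h       # integral of N_b r dr
        total = r1 * c + c**2 / 2.0                        # integral of r dr
        f[2 * na + 1] -= 2.0 * np.pi * (total - moment)
        f[2 * nb + 1] -= 2.0 * np.pi * moment
    return f


def _fixed_dofs(mesh: AxisymmetricMesh, bc: BoundaryConditionSpec) -> np.ndarray:
    nr, nz = mesh.nr, mesh.nz
    fixed = []
    axis_nodes = np.arange(0, (nz + 1) * (nr + 1), nr + 1)
    fixed.append(2 * axis_nodes)                          # u_r = 0 on the axis
    bottom_nodes = np.arange(nr + 1)
    fixed.append(2 * bottom_nodes + 1)                    # u_z = 0 at the bottom
    if bc.bottom_fix is BottomFix.ALL_DIRECTIONS:
        fixed.append(2 * bottom_nodes)
    if bc.side_fix is SideFix.HORIZONTAL:
        side_nodes = np.arange(nr, (nz + 1) * (nr + 1), nr + 1)
        fixed.append(2 * side_nodes)
    return np.unique(np.concatenate(fixed))


# ---------------------------------------------------------------------------
# forward solve
# ---------------------------------------------------------------------------

def run_forward(mesh: AxisymmetricMesh, material: MaterialSpec,
                load: LoadingProtocol, bc: BoundaryConditionSpec,
                dt_ramp: float | None = None,
                dt_hold: float = 0.1) -> StrainFieldHistory:
    """Solve the ramp-and-hold creep problem and return centroid strain histories.

    dt_ramp defaults to ramp_time / 10.  Both phases use uniform steps, so a
    single sparse factorisation per phase is reused for every step.
    """
    if dt_ramp is None:
        dt_ramp = load.ramp_time / 10.0
    if dt_ramp > load.ramp_time / 10.0 + 1e-12:
        raise DomainError("dt_ramp must be <= ramp_time / 10")
    if dt_hold > material.tau_R / 10.0 + 1e-12:
        raise DomainError("dt_hold must be <= tau_R / 10")

    n_ramp = max(10, round(load.ramp_time / dt_ramp))
    dt_ramp = load.ramp_time / n_ramp
    n_hold = max(1, round(load.hold_time / dt_hold))
    dt_hold = load.hold_time / n_hold

    K_bulk = material.bulk_modulus
    G_inf = material.shear_modulus_longterm
    dG = material.shear_modulus_instant - G_inf     # = G0 * g
    tau_R = material.tau_R

    Bbar_gp, w_gp, Bbar_c, dofmat = _element_operators(mesh)
    n_dof = 2 * mesh.n_nodes
    A_vol = _assemble_global(Bbar_gp, w_gp, dofmat, np.outer(_M_VOL, _M_VOL), n_dof)
    A_dev = _assemble_global(Bbar_gp, w_gp, dofmat, 2.0 * _J_DEV, n_dof)

    f_unit = _traction_vector(mesh, load.loaded_extent(mesh.radius))
    fixed = _fixed_dofs(mesh, bc)
    free = np.setdiff1d(np.arange(n_dof), fixed, assume_unique=True)
    bottom_z = 2 * np.arange(mesh.nr + 1) + 1
    loaded_area = np.pi * load.loaded_extent(mesh.radius) ** 2

    n_times = 1 + n_ramp + n_hold
    times = np.empty(n_times)
    times[: n_ramp + 1] = np.linspace(0.0, load.ramp_time, n_ramp + 1)
    times[n_ramp:] = load.ramp_time + np.linspace(0.0, load.hold_time, n_hold + 1)
    pressure = load.p_max * np.minimum(times / load.ramp_time, 1.0)

    strains = np.zeros((n_times, mesh.n_elements, 4))
    residuals = np.zeros(n_times)

    # state
    u = np.zeros(n_dof)
    eps_gp = np.zeros((mesh.n_elements, 4, 4))      # (el, gp, comp), physical sign
    q_gp = np.zeros_like(eps_gp)                    # deviatoric history stress

    def internal_force(stress_gp):
        Fe = np.einsum("egai,ega,eg->ei", Bbar_gp, stress_gp, w_gp)
        F = np.zeros(n_dof)
        np.add.at(F, dofmat, Fe)
        return F

    step = 0
    for dt, n_steps in [(dt_ramp, n_ramp), (dt_hold, n_hold)]:
        alpha = dt / tau_R
        decay = np.exp(-alpha)
        beta = (1.0 - decay) / alpha
        G_eff = G_inf + dG * beta
        K_glob = (K_bulk * A_vol + G_eff * A_dev).tocsc()
        try:
            lu = spla.splu(K_glob[free, :][:, free].tocsc())
        except RuntimeError as exc:  # pragma: no cover - guarded by BC invariants
            raise SolverError(
                "singular stiffness matrix: the boundary conditions leave a "
                "rigid-body mode (vertical translation) unconstrained") from exc

        for _ in range(n_steps):
            step += 1
            # known part of the deviatoric stress at the new time
            dev_eps = np.einsum("ab,egb->ega", _J_DEV, eps_gp)
            s_hat = decay * q_gp - 2.0 * dG * beta * dev_eps
            F_hist = internal_force(s_hat)
            F_ext = pressure[step] * f_unit
            rhs = (F_ext - F_hist)[free]
            u_free = lu.solve(rhs)
            if not np.all(np.isfinite(u_free)):
                raise SolverError(f"non-finite solution at step {step}")
            u[:] = 0.0
            u[free] = u_free

            ue = u[dofmat]                                       # (nel, 8)
            eps_new = np.einsum("egai,ei->ega", Bbar_gp, ue)
            dev_new = np.einsum("ab,egb->ega", _J_DEV, eps_new)
            q_gp = s_hat + 2.0 * dG * beta * dev_new
            eps_gp = eps_new

            # record centroid strains, compression-positive
            strains[step] = -np.einsum("eai,ei->ea", Bbar_c, ue)

            # equilibrium diagnostic from the full internal force vector
            sigma_gp = (K_bulk * np.einsum("egb,b->eg", eps_new, _M_VOL)[:, :, None]
                        * _M_VOL[None, None, :] + 2.0 * G_inf * dev_new + q_gp)
            F_int = internal_force(sigma_gp)
            applied = pressure[step] * loaded_area
            if applied > 0:
                # vertical reactions at the constrained bottom must balance the load
                residuals[step] = abs(F_int[bottom_z].sum() - applied) / applied

    return StrainFieldHistory(times=times, strains=strains, pressure=pressure,
                              mesh=mesh, material=material, load=load, bc=bc,
                              reaction_residuals=residuals)


# ---------------------------------------------------------------------------
# curve extraction
# ---------------------------------------------------------------------------

def extract_creep_curves(hist: StrainFieldHistory,
                         imaging_radius: float) -> list[CreepCurve]:
    """Hold-phase creep curves for every element with centroid r <= imaging_radius.

    Times are re-zeroed at the instant the pressure first reaches its
    plateau; sigma0 is the applied p_max (the nominal-stress assumption of
    the imaging method).
    """
    mesh = hist.mesh
    if imaging_radius > mesh.radius + 1e-12:
        raise DomainError("imaging_radius exceeds the mesh radius")
    t_ramp = hist.load.ramp_time
    k0 = int(np.argmin(np.abs(hist.times - t_ramp)))
    if abs(hist.times[k0] - t_ramp) > 1e-9:
        raise DomainError("history does not contain the end-of-ramp instant")
    times = hist.times[k0:] - t_ramp
    i_idx, j_idx = mesh.element_grid_indices()
    sel = np.flatnonzero(mesh.centroids[:, 0] <= imaging_radius)
    curves = []
    for e in sel:
        curves.append(CreepCurve(times=times.copy(),
                                 eps_zz=hist.eps_zz[k0:, e].copy(),
                                 sigma0=hist.load.p_max,
                                 element=(int(i_idx[e]), int(j_idx[e])),
                                 ramp_time=hist.load.ramp_time))
    return curves
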