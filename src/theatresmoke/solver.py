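"""Steady buoyant RANS solver for the ventilated theatre.

Finite-volume discretization on the structured mesh of :mod:`.scene`:

* incompressible continuity + momentum with the gravity term carrying the
  full ideal-gas density variation rho(T) = rho_ref * T_ref / T (the source
  is ~470 K above ambient, far outside the Boussinesq range, while Mach
  numbers are ~1e-4, so density variation matters only through buoyancy);
* standard k-epsilon closure with eddy viscosity mu_t = rho C_mu k^2/eps
  and standard wall functions;
* an energy equation for temperature with effective diffusivity
  mu/sigma_T + mu_t/sigma_tT;
* passive species transport for the waste-gas components.

Pressure-velocity coupling is SIMPLEC on a collocated grid with
Rhie-Chow face-flux interpolation; convection is first-order upwind
(bounded), diffusion central.  Residuals are normalized by their
first-iteration values, matching the usual "residual < tol" convergence
statement of commercial solvers.

The smoke source is a volumetric mass/momentum/enthalpy/species source in
the single cell containing the incision point: the physical source (a few
cm across) is sub-grid at any room-scale resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .empirical import SourceSpec
from .scene import Mesh, Patch

__all__ = [
    "GasProperties", "TurbulenceConstants", "BoundaryConditionSet",
    "SolverSettings", "SourceTerms", "FieldState", "SolverFault",
    "inlet_turbulence", "effective_viscosity", "production_Gk",
    "assemble_source", "wall_treatment", "solve_steady",
    "solve_passive_scalar", "mass_balance", "solve_conv_diff_1d",
]

KELVIN = 273.15
GRAVITY = 9.81
R_GAS = 8.314462618
VON_KARMAN = 0.41
WALL_E = 9.8
YSTAR_LAM = 11.63   # crossover of linear and log laws


class SolverFault(RuntimeError):
    """Raised on divergence or invalid solver state; carries diagnostics."""

    def __init__(self, message: str, history=None, where=None):
        super().__init__(message)
        self.history = history
        self.where = where


@dataclass(frozen=True)
class GasProperties:
    """Carrier-gas (air) properties.

    Documented assumption: the supporting material table of the original
    study is unavailable, so standard dry-air values near 300 K are used
    and exposed in config.
    """

    mu: float = 1.85e-5          # Pa s
    cp: float = 1006.0           # J/(kg K)
    molar_mass: float = 0.02896  # kg/mol
    pressure: float = 101325.0   # Pa
    T_ref: float = 27.0 + KELVIN  # K, density reference (ambient)

    @property
    def rho_ref(self) -> float:
        return self.pressure * self.molar_mass / (R_GAS * self.T_ref)

    def rho(self, T_kelvin):
        """Ideal-gas density at constant pressure (used in the gravity term)."""
        return self.rho_ref * self.T_ref / np.asarray(T_kelvin, dtype=float)


@dataclass(frozen=True)
class TurbulenceConstants:
    """k-epsilon closure constants; defaults as used by the study
    (C1=1.43, C2=1.93, sigma_eps=1.43 — slightly off the canonical
    1.44/1.92/1.3 set, which remains selectable)."""

    C1: float = 1.43
    C2: float = 1.93
    Cmu: float = 0.09
    sigma_k: float = 1.0
    sigma_eps: float = 1.43
    sigma_T: float = 1.00
    sigma_tT: float = 0.9

    def __post_init__(self):
        for name in ("C1", "C2", "Cmu", "sigma_k", "sigma_eps", "sigma_T", "sigma_tT"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def canonical(cls) -> "TurbulenceConstants":
        return cls(C1=1.44, C2=1.92, sigma_eps=1.3)


@dataclass(frozen=True)
class BoundaryConditionSet:
    """Theatre boundary conditions.

    The ceiling inlet feeds a uniform downward curtain; the two low wall
    slots are fixed-pressure outlets; side walls are no-slip with a Robin
    (third-kind) heat condition to a warmer exterior, which sustains the
    weak natural-convection updraft observed along outlet-free walls;
    ceiling, floor and table are no-slip adiabatic.
    """

    inlet_velocity: float = 0.096     # m/s, downward
    inlet_temp: float = 27.0          # degC
    turb_intensity: float = 0.037
    length_scale_width: float = 2.4   # m; l = 0.07 * this
    wall_htc: float = 1.5             # W/(m^2 K), side walls
    wall_exterior_temp: float = 30.0  # degC

    def __post_init__(self):
        if self.inlet_velocity <= 0:
            raise ValueError("inlet velocity must be positive")
        if not 0 < self.turb_intensity < 1:
            raise ValueError("turbulence intensity must lie in (0,1)")

    @property
    def length_scale(self) -> float:
        return 0.07 * self.length_scale_width


@dataclass(frozen=True)
class SolverSettings:
    """Iteration control.  tolerance=1e-4 matches the study's convergence
    criterion; 1e-3 is adequate for coarse desk-scale grids."""

    tolerance: float = 1e-4
    max_iterations: int = 4000
    relax_momentum: float = 0.7
    relax_pressure: float = 0.3
    relax_scalar: float = 0.5
    #: pseudo-transient time step (s): an implicit inertial term that
    #: conditions the nearly stagnant regions; cancels identically at
    #: steady state (converged fields are insensitive to it).
    pseudo_dt: float = 2.0
    #: optional deferred-correction blend toward central-difference
    #: convection for momentum and energy (0 = pure first-order upwind,
    #: 1 = full central).  Upwind is the default: it is bounded and, on
    #: the buoyant-plume benchmark cases, at least as accurate as the
    #: partially centred variants, which converge to slightly lower ascent
    #: heights (or, at full blend, limit-cycle).
    central_blend: float = 0.0
    min_iterations: int = 200
    #: velocity magnitude (m/s) beyond which the solve is declared divergent
    velocity_bound: float = 50.0
    #: relative tolerance of the inner pressure-correction CG solve per
    #: outer iteration (tightened automatically for the final projections)
    pressure_rtol: float = 1e-2

    def __post_init__(self):
        for name in ("relax_momentum", "relax_pressure", "relax_scalar"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in (0,1]")
        if self.tolerance <= 0 or self.pseudo_dt <= 0:
            raise ValueError("tolerance and pseudo_dt must be positive")
        if not 0.0 <= self.central_blend <= 1.0:
            raise ValueError("central_blend must lie in [0, 1]")


@dataclass
class SourceTerms:
    """Per-run volumetric source terms of the incision smoke inlet."""

    cell: tuple[int, int, int]
    mdot: float                      # kg/s of waste gas
    w_injection: float               # m/s vertical injection velocity
    temperature: float               # K
    species_mass_fractions: dict[str, float]
    tar_rate: float                  # kg/s
    particle_rate: float             # kg/s


@dataclass
class FieldState:
    """Converged (or partially converged) per-cell fields."""

    mesh: Mesh
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    p: np.ndarray
    T: np.ndarray                    # K
    k: np.ndarray
    eps: np.ndarray
    species: dict[str, np.ndarray] = field(default_factory=dict)
    c_tar: np.ndarray | None = None       # g/m^3
    c_particle: np.ndarray | None = None  # g/m^3
    converged: bool = False
    residual_history: dict[str, list[float]] = field(default_factory=dict)
    fluxes: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
    source: SourceTerms | None = None
    bc: "BoundaryConditionSet | None" = None

    @property
    def T_celsius(self) -> np.ndarray:
        return self.T - KELVIN


# ---------------------------------------------------------------------------
# small closed-form operations

def inlet_turbulence(V_in: float, Ti: float, length_scale: float,
                     Cmu: float = 0.09) -> tuple[float, float]:
    """Inlet k and epsilon: k = 1.5 (V Ti)^2, eps = Cmu^0.75 k^1.5 / l."""
    if V_in <= 0 or Ti <= 0 or Cmu <= 0:
        raise ValueError("inlet turbulence requires positive V_in, Ti, Cmu")
    if length_scale <= 0:
        raise ValueError("turbulence length scale must be positive")
    k = 1.5 * (V_in * Ti) ** 2
    eps = Cmu ** 0.75 * k ** 1.5 / length_scale
    return k, eps


def effective_viscosity(k, eps, props: GasProperties,
                        constants: TurbulenceConstants):
    """mu_eff = mu + rho C_mu k^2 / eps, bounded below by mu."""
    k = np.asarray(k, dtype=float)
    eps = np.asarray(eps, dtype=float)
    if np.any(eps <= 0):
        where = np.argwhere(np.atleast_1d(eps) <= 0)
        raise SolverFault(f"non-positive dissipation at cells {where[:5].tolist()}",
                          where=where)
    mu_t = props.rho_ref * constants.Cmu * k ** 2 / eps
    return props.mu + mu_t


def _grad(phi: np.ndarray, d: tuple[float, float, float], axis: int) -> np.ndarray:
    """Central-difference gradient with one-sided stencils at the ends."""
    g = np.gradient(phi, d[axis], axis=axis)
    return g


def production_Gk(u, v, w, d, mu_t) -> np.ndarray:
    """Shear production G_k = mu_t (du_j/dx_i)(du_i/dx_j + du_j/dx_i).

    Central differences; one-sided at domain ends.  ``d`` is either a
    per-axis spacing tuple or a tuple of centre-coordinate arrays (graded
    meshes).  Vanishes for uniform flow and for rigid rotation (the
    contraction picks out the symmetric part of the velocity gradient).
    """
    comps = (u, v, w)
    grads = [[_grad(c, d, ax) for ax in range(3)] for c in comps]
    s = np.zeros_like(np.asarray(u, dtype=float))
    for i in range(3):
        for j in range(3):
            s += grads[j][i] * (grads[i][j] + grads[j][i])
    return mu_t * s


T_STP = 273.15   # K; the measured waste-gas flows are STP-corrected


def assemble_source(source: SourceSpec, mesh: Mesh,
                    props: GasProperties | None = None) -> SourceTerms:
    """Turn a :class:`SourceSpec` into volumetric source terms.

    The measured net waste-gas flow is reported at STP, so the injected
    mass rate is the STP gas density times that flow; the gas enters the
    incision cell at the source (tip) temperature, and its actual
    volumetric rate there follows from the ideal-gas expansion.  Momentum,
    enthalpy and species sources are consistent with that mass flux
    entering vertically.
    """
    from .scene import locate_cell

    props = props or GasProperties()
    cell = locate_cell(mesh, source.position)
    if not mesh.fluid[cell]:
        raise ValueError(f"smoke source position {source.position} lies in a solid cell")
    T_k = source.temperature + KELVIN
    rho_stp = props.pressure * props.molar_mass / (R_GAS * T_STP)
    mdot = rho_stp * source.volume_flow
    hot_volume_flow = mdot / float(props.rho(T_k))
    cell_area = mesh.widths(0)[cell[0]] * mesh.widths(1)[cell[1]]
    w_inj = hot_volume_flow / cell_area
    return SourceTerms(
        cell=cell, mdot=mdot, w_injection=w_inj, temperature=T_k,
        species_mass_fractions=dict(source.species_mass_fractions),
        tar_rate=source.tar_rate * 1e-3, particle_rate=source.particle_rate * 1e-3)


def wall_treatment(u_tangential: float, k_cell: float, y: float,
                   props: GasProperties, constants: TurbulenceConstants,
                   ) -> tuple[float, float, float]:
    """Standard wall function at one wall-adjacent cell.

    Returns ``(tau_w, c_w, eps_wall)`` where ``tau_w = c_w * u_tangential``
    is the wall shear stress, the linear law applies below y* = 11.63 and
    the log law above, and ``eps_wall = Cmu^0.75 k^1.5/(kappa y)`` is the
    equilibrium near-wall dissipation.
    """
    if y <= 0:
        raise ValueError("wall distance must be positive")
    rho, mu = props.rho_ref, props.mu
    k_cell = max(k_cell, 1e-14)
    ustar = constants.Cmu ** 0.25 * math.sqrt(k_cell)
    y_star = rho * ustar * y / mu
    if y_star > YSTAR_LAM:
        c_w = rho * ustar * VON_KARMAN / math.log(WALL_E * y_star)
    else:
        c_w = mu / y
    eps_wall = constants.Cmu ** 0.75 * k_cell ** 1.5 / (VON_KARMAN * y)
    return c_w * u_tangential, c_w, eps_wall


def _wall_coefficient(k_field: np.ndarray, y: float, props: GasProperties,
                      constants: TurbulenceConstants) -> np.ndarray:
    """Vectorized ``c_w`` of :func:`wall_treatment` for a k-field slab."""
    rho, mu = props.rho_ref, props.mu
    k = np.maximum(k_field, 1e-14)
    ustar = constants.Cmu ** 0.25 * np.sqrt(k)
    y_star = rho * ustar * y / mu
    log_branch = rho * ustar * VON_KARMAN / np.log(WALL_E * np.maximum(y_star, 1.0 + 1e-9))
    return np.where(y_star > YSTAR_LAM, log_branch, mu / y)


# ---------------------------------------------------------------------------
# linear algebra on the 7-point stencil

def _try_numba():
    try:
        import numba  # noqa: F401
        return True
    except Exception:
        return False


_HAVE_NUMBA = _try_numba()

if _HAVE_NUMBA:
    import numba

    @numba.njit(cache=False, fastmath=True)
    def _rb_gs(ap, aW, aE, aS, aN, aB, aT, b, phi, sweeps):
        nx, ny, nz = phi.shape
        for s in range(sweeps):
            for color in range(2):
                for i in range(nx):
                    for j in range(ny):
                        for kk in range(nz):
                            if (i + j + kk) % 2 != color:
                                continue
                            acc = b[i, j, kk]
                            if i > 0:
                                acc += aW[i, j, kk] * phi[i - 1, j, kk]
                            if i < nx - 1:
                                acc += aE[i, j, kk] * phi[i + 1, j, kk]
                            if j > 0:
                                acc += aS[i, j, kk] * phi[i, j - 1, kk]
                            if j < ny - 1:
                                acc += aN[i, j, kk] * phi[i, j + 1, kk]
                            if kk > 0:
                                acc += aB[i, j, kk] * phi[i, j, kk - 1]
                            if kk < nz - 1:
                                acc += aT[i, j, kk] * phi[i, j, kk + 1]
                            phi[i, j, kk] = acc / ap[i, j, kk]
else:
    def _rb_gs(ap, aW, aE, aS, aN, aB, aT, b, phi, sweeps):
        # Jacobi fallback (more sweeps, same fixed point)
        for _ in range(3 * sweeps):
            acc = b.copy()
            acc[1:] += aW[1:] * phi[:-1]
            acc[:-1] += aE[:-1] * phi[1:]
            acc[:, 1:] += aS[:, 1:] * phi[:, :-1]
            acc[:, :-1] += aN[:, :-1] * phi[:, 1:]
            acc[:, :, 1:] += aB[:, :, 1:] * phi[:, :, :-1]
            acc[:, :, :-1] += aT[:, :, :-1] * phi[:, :, 1:]
            phi[...] = acc / ap


def _stencil_matrix(ap, aW, aE, aS, aN, aB, aT):
    nx, ny, nz = ap.shape
    n = nx * ny * nz
    idx = np.arange(n).reshape(nx, ny, nz)
    rows, cols, vals = [idx.ravel()], [idx.ravel()], [ap.ravel()]

    def link(a, shift_rows, shift_cols):
        rows.append(shift_rows.ravel())
        cols.append(shift_cols.ravel())
        vals.append(-a.ravel())

    link(aW[1:], idx[1:], idx[:-1])
    link(aE[:-1], idx[:-1], idx[1:])
    link(aS[:, 1:], idx[:, 1:], idx[:, :-1])
    link(aN[:, :-1], idx[:, :-1], idx[:, 1:])
    link(aB[:, :, 1:], idx[:, :, 1:], idx[:, :, :-1])
    link(aT[:, :, :-1], idx[:, :, :-1], idx[:, :, 1:])
    return sp.csr_matrix((np.concatenate(vals),
                          (np.concatenate(rows), np.concatenate(cols))),
                         shape=(n, n))


def _solve_direct(ap, aW, aE, aS, aN, aB, aT, b):
    A = _stencil_matrix(ap, aW, aE, aS, aN, aB, aT)
    x = spla.spsolve(A.tocsc(), b.ravel())
    return x.reshape(ap.shape)


def _stencil_matvec_numpy(ap, aW, aE, aS, aN, aB, aT, x):
    y = ap * x
    y[1:] -= aW[1:] * x[:-1]
    y[:-1] -= aE[:-1] * x[1:]
    y[:, 1:] -= aS[:, 1:] * x[:, :-1]
    y[:, :-1] -= aN[:, :-1] * x[:, 1:]
    y[:, :, 1:] -= aB[:, :, 1:] * x[:, :, :-1]
    y[:, :, :-1] -= aT[:, :, :-1] * x[:, :, 1:]
    return y


if _HAVE_NUMBA:
    @numba.njit(cache=False, fastmath=True)
    def _stencil_matvec(ap, aW, aE, aS, aN, aB, aT, x):
        nx, ny, nz = x.shape
        y = np.empty_like(x)
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    acc = ap[i, j, k] * x[i, j, k]
                    if i > 0:
                        acc -= aW[i, j, k] * x[i - 1, j, k]
                    if i < nx - 1:
                        acc -= aE[i, j, k] * x[i + 1, j, k]
                    if j > 0:
                        acc -= aS[i, j, k] * x[i, j - 1, k]
                    if j < ny - 1:
                        acc -= aN[i, j, k] * x[i, j + 1, k]
                    if k > 0:
                        acc -= aB[i, j, k] * x[i, j, k - 1]
                    if k < nz - 1:
                        acc -= aT[i, j, k] * x[i, j, k + 1]
                    y[i, j, k] = acc
        return y
else:
    _stencil_matvec = _stencil_matvec_numpy


def _cg_stencil_numpy(ap, aW, aE, aS, aN, aB, aT, b, x0=None,
                      rtol=1e-8, maxiter=2000):
    """Jacobi-preconditioned CG for the (SPD) pressure-correction stencil."""
    x = np.zeros_like(b) if x0 is None else x0.copy()
    bnorm = float(np.linalg.norm(b))
    if bnorm == 0.0:
        return x
    r = b - _stencil_matvec_numpy(ap, aW, aE, aS, aN, aB, aT, x)
    z = r / ap
    p = z.copy()
    rz = float((r * z).sum())
    for _ in range(maxiter):
        Apv = _stencil_matvec_numpy(ap, aW, aE, aS, aN, aB, aT, p)
        alpha = rz / float((p * Apv).sum())
        x += alpha * p
        r -= alpha * Apv
        if np.linalg.norm(r) <= rtol * bnorm:
            break
        z = r / ap
        rz_new = float((r * z).sum())
        p = z + (rz_new / rz) * p
        rz = rz_new
    return x


if _HAVE_NUMBA:
    @numba.njit(cache=False, fastmath=True)
    def _cg_stencil(ap, aW, aE, aS, aN, aB, aT, b, x0=None,
                    rtol=1e-8, maxiter=2000):
        x = np.zeros_like(b)
        bnorm = np.sqrt((b * b).sum())
        if bnorm == 0.0:
            return x
        r = b - _stencil_matvec(ap, aW, aE, aS, aN, aB, aT, x)
        z = r / ap
        p = z.copy()
        rz = (r * z).sum()
        for _ in range(maxiter):
            Apv = _stencil_matvec(ap, aW, aE, aS, aN, aB, aT, p)
            alpha = rz / (p * Apv).sum()
            x += alpha * p
            r -= alpha * Apv
            if np.sqrt((r * r).sum()) <= rtol * bnorm:
                break
            z = r / ap
            rz_new = (r * z).sum()
            p = z + (rz_new / rz) * p
            rz = rz_new
        return x
else:
    _cg_stencil = _cg_stencil_numpy


def _residual(ap, aW, aE, aS, aN, aB, aT, b, phi, mask=None) -> float:
    r = ap * phi - b
    r[1:] -= aW[1:] * phi[:-1]
    r[:-1] -= aE[:-1] * phi[1:]
    r[:, 1:] -= aS[:, 1:] * phi[:, :-1]
    r[:, :-1] -= aN[:, :-1] * phi[:, 1:]
    r[:, :, 1:] -= aB[:, :, 1:] * phi[:, :, :-1]
    r[:, :, :-1] -= aT[:, :, :-1] * phi[:, :, 1:]
    if mask is not None:
        r = r[mask]
    return float(np.abs(r).sum())


# ---------------------------------------------------------------------------
# the solver proper

class _Discretization:
    """Shared geometric/masking machinery for one mesh."""

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        nx, ny, nz = mesh.n
        self.V = mesh.volumes
        w = [mesh.widths(a) for a in range(3)]
        # per-cell face areas (broadcast to (nx, ny, nz)) and half widths
        self.A = (
            np.broadcast_to(mesh.face_areas(0)[None, :, :], mesh.n),
            np.broadcast_to(mesh.face_areas(1)[:, None, :], mesh.n),
            np.broadcast_to(mesh.face_areas(2)[:, :, None], mesh.n),
        )
        self.halfw = (
            np.broadcast_to((w[0] / 2)[:, None, None], mesh.n),
            np.broadcast_to((w[1] / 2)[None, :, None], mesh.n),
            np.broadcast_to((w[2] / 2)[None, None, :], mesh.n),
        )
        # centre-to-centre distances across every face (half cell at the
        # domain boundary)
        c = [mesh.centers(a) for a in range(3)]
        self.delta = tuple(
            np.concatenate([[w[a][0] / 2], np.diff(c[a]), [w[a][-1] / 2]])
            for a in range(3))
        self.fluid = mesh.fluid
        self.solid = ~mesh.fluid
        # interior fluid-fluid face masks
        self.int_x = (mesh.fx[1:-1] == Patch.INTERIOR) & mesh.fluid[1:] & mesh.fluid[:-1]
        self.int_y = (mesh.fy[:, 1:-1] == Patch.INTERIOR) & mesh.fluid[:, 1:] & mesh.fluid[:, :-1]
        self.int_z = (mesh.fz[:, :, 1:-1] == Patch.INTERIOR) & mesh.fluid[:, :, 1:] & mesh.fluid[:, :, :-1]
        # per-cell boundary-face label views: west/east/south/north/bottom/top
        self.face_labels = {
            ("x", 0): mesh.fx[:-1], ("x", 1): mesh.fx[1:],
            ("y", 0): mesh.fy[:, :-1], ("y", 1): mesh.fy[:, 1:],
            ("z", 0): mesh.fz[:, :, :-1], ("z", 1): mesh.fz[:, :, 1:],
        }

    def cell_has(self, label: int):
        """Dict (axis, side) -> bool mask of fluid cells with that face label."""
        out = {}
        for (ax, side), lab in self.face_labels.items():
            out[(ax, side)] = (lab == label) & self.fluid
        return out

    def face_mean(self, phi: np.ndarray, gamma_like=True):
        """Arithmetic means on interior faces; zeros elsewhere."""
        nx, ny, nz = self.mesh.n
        gx = np.zeros((nx + 1, ny, nz))
        gy = np.zeros((nx, ny + 1, nz))
        gz = np.zeros((nx, ny, nz + 1))
        gx[1:-1][self.int_x] = 0.5 * (phi[1:] + phi[:-1])[self.int_x]
        gy[:, 1:-1][self.int_y] = 0.5 * (phi[:, 1:] + phi[:, :-1])[self.int_y]
        gz[:, :, 1:-1][self.int_z] = 0.5 * (phi[:, :, 1:] + phi[:, :, :-1])[self.int_z]
        return gx, gy, gz


def _upwind_coeffs(disc: _Discretization, Fx, Fy, Fz, Dx, Dy, Dz):
    """7-point coefficients for upwind convection + central diffusion.

    ``F*`` are face mass fluxes positive along +axis; ``D*`` face diffusion
    conductances (Gamma_f A/delta), zero on non-interior faces.  Domain
    boundary faces are excluded here: their convection/diffusion enters
    through the explicit boundary-condition terms of each equation.
    """
    Fx = Fx.copy(); Fx[0] = 0.0; Fx[-1] = 0.0
    Fy = Fy.copy(); Fy[:, 0] = 0.0; Fy[:, -1] = 0.0
    Fz = Fz.copy(); Fz[:, :, 0] = 0.0; Fz[:, :, -1] = 0.0
    aW = Dx[:-1] + np.maximum(Fx[:-1], 0.0)
    aE = Dx[1:] + np.maximum(-Fx[1:], 0.0)
    aS = Dy[:, :-1] + np.maximum(Fy[:, :-1], 0.0)
    aN = Dy[:, 1:] + np.maximum(-Fy[:, 1:], 0.0)
    aB = Dz[:, :, :-1] + np.maximum(Fz[:, :, :-1], 0.0)
    aT = Dz[:, :, 1:] + np.maximum(-Fz[:, :, 1:], 0.0)
    ap = (Dx[:-1] + np.maximum(-Fx[:-1], 0.0)
          + Dx[1:] + np.maximum(Fx[1:], 0.0)
          + Dy[:, :-1] + np.maximum(-Fy[:, :-1], 0.0)
          + Dy[:, 1:] + np.maximum(Fy[:, 1:], 0.0)
          + Dz[:, :, :-1] + np.maximum(-Fz[:, :, :-1], 0.0)
          + Dz[:, :, 1:] + np.maximum(Fz[:, :, 1:], 0.0))
    return ap, aW, aE, aS, aN, aB, aT


def _mask_solid(ap, aW, aE, aS, aN, aB, aT, b, fluid, value=0.0):
    solid = ~fluid
    for a in (aW, aE, aS, aN, aB, aT):
        a[solid] = 0.0
    ap[solid] = 1.0
    b[solid] = value


class RansSolver:
    """SIMPLEC outer iteration on one mesh/BC/source configuration."""

    SPECIES = ("CO", "CO2", "CH4", "NH3")

    def __init__(self, mesh: Mesh, bc: BoundaryConditionSet,
                 source: SourceTerms | None,
                 settings: SolverSettings | None = None,
                 constants: TurbulenceConstants | None = None,
                 props: GasProperties | None = None):
        self.mesh = mesh
        self.bc = bc
        self.src = source
        self.settings = settings or SolverSettings()
        self.const = constants or TurbulenceConstants()
        self.props = props or GasProperties()
        self.disc = _Discretization(mesh)
        self.d = mesh.d                 # mean spacings (diagnostics)
        self.V = self.disc.V            # per-cell volumes

        self.T_in = bc.inlet_temp + KELVIN
        self.T_ext = bc.wall_exterior_temp + KELVIN
        self.k_in, self.eps_in = inlet_turbulence(
            bc.inlet_velocity, bc.turb_intensity, bc.length_scale, self.const.Cmu)

        # boundary masks per label
        self.inlet_cells = self.disc.cell_has(Patch.INLET)
        self.outlet_cells = self.disc.cell_has(Patch.OUTLET)
        self._pressure_rtol = self.settings.pressure_rtol
        self.wall_cells = {}
        for lab in (Patch.SIDEWALL, Patch.CEILING, Patch.FLOOR, Patch.TABLE):
            self.wall_cells[lab] = self.disc.cell_has(lab)
        # any no-slip wall face (incl. ceiling outside the inlet)
        self.any_wall = {key: np.zeros(mesh.n, dtype=bool)
                         for key in self.inlet_cells}
        for lab, masks in self.wall_cells.items():
            for key, m in masks.items():
                self.any_wall[key] |= m

        self._init_state()

    # ------------------------------------------------------------------
    def _init_state(self):
        n = self.mesh.n
        self._scales = {}
        z = lambda: np.zeros(n)
        self.u, self.v, self.w = z(), z(), z()
        self.p = z()
        self.T = np.full(n, self.T_in)
        self.k = np.full(n, max(self.k_in, 1e-10))
        self.eps = np.full(n, max(self.eps_in, 1e-12))
        rho = self.props.rho_ref
        nx, ny, nz = n
        self.Fx = np.zeros((nx + 1, ny, nz))
        self.Fy = np.zeros((nx, ny + 1, nz))
        self.Fz = np.zeros((nx, ny, nz + 1))
        # fixed inlet mass flux (downward through top faces)
        self.inlet_flux_faces = (self.mesh.fz[:, :, -1] == Patch.INLET)
        Az = self.mesh.face_areas(2)
        self.Fz[:, :, -1][self.inlet_flux_faces] = \
            -rho * self.bc.inlet_velocity * Az[self.inlet_flux_faces]
        self.mdot_in = rho * self.bc.inlet_velocity \
            * float(Az[self.inlet_flux_faces].sum())

    # ------------------------------------------------------------------
    def _face_diffusion(self, gamma: np.ndarray):
        gx, gy, gz = self.disc.face_mean(gamma)
        dlx, dly, dlz = self.disc.delta
        mesh = self.mesh
        return (gx * mesh.face_areas(0)[None] / dlx[:, None, None],
                gy * mesh.face_areas(1)[:, None, :] / dly[None, :, None],
                gz * mesh.face_areas(2)[:, :, None] / dlz[None, None, :])

    def _face_pressures(self, p):
        """Face pressure arrays with wall zero-gradient / outlet p=0."""
        mesh = self.mesh
        nx, ny, nz = mesh.n
        px = np.zeros((nx + 1, ny, nz))
        py = np.zeros((nx, ny + 1, nz))
        pz = np.zeros((nx, ny, nz + 1))
        px[1:-1] = 0.5 * (p[1:] + p[:-1])
        py[:, 1:-1] = 0.5 * (p[:, 1:] + p[:, :-1])
        pz[:, :, 1:-1] = 0.5 * (p[:, :, 1:] + p[:, :, :-1])
        px[0], px[-1] = p[0], p[-1]
        py[:, 0], py[:, -1] = p[:, 0], p[:, -1]
        pz[:, :, 0], pz[:, :, -1] = p[:, :, 0], p[:, :, -1]
        # solid-face zero-gradient: copy fluid cell value
        fsx = ~self.disc.int_x & (mesh.fx[1:-1] != Patch.INTERIOR)
        px[1:-1][fsx & mesh.fluid[:-1]] = p[:-1][fsx & mesh.fluid[:-1]]
        px[1:-1][fsx & mesh.fluid[1:]] = p[1:][fsx & mesh.fluid[1:]]
        fsy = ~self.disc.int_y & (mesh.fy[:, 1:-1] != Patch.INTERIOR)
        py[:, 1:-1][fsy & mesh.fluid[:, :-1]] = p[:, :-1][fsy & mesh.fluid[:, :-1]]
        py[:, 1:-1][fsy & mesh.fluid[:, 1:]] = p[:, 1:][fsy & mesh.fluid[:, 1:]]
        fsz = ~self.disc.int_z & (mesh.fz[:, :, 1:-1] != Patch.INTERIOR)
        pz[:, :, 1:-1][fsz & mesh.fluid[:, :, :-1]] = p[:, :, :-1][fsz & mesh.fluid[:, :, :-1]]
        pz[:, :, 1:-1][fsz & mesh.fluid[:, :, 1:]] = p[:, :, 1:][fsz & mesh.fluid[:, :, 1:]]
        # pressure outlets: p = 0 on outlet faces
        py[:, 0][mesh.fy[:, 0] == Patch.OUTLET] = 0.0
        py[:, -1][mesh.fy[:, -1] == Patch.OUTLET] = 0.0
        return px, py, pz

    @property
    def _cell_widths(self):
        mesh = self.mesh
        return (mesh.widths(0)[:, None, None],
                mesh.widths(1)[None, :, None],
                mesh.widths(2)[None, None, :])

    @property
    def _interior_deltas(self):
        """Centre-to-centre distances across interior faces, broadcastable."""
        dlx, dly, dlz = self.disc.delta
        return (dlx[1:-1, None, None], dly[None, 1:-1, None],
                dlz[None, None, 1:-1])

    @property
    def _face_area_arrays(self):
        mesh = self.mesh
        return (mesh.face_areas(0)[None, :, :],
                mesh.face_areas(1)[:, None, :],
                mesh.face_areas(2)[:, :, None])

    def _pressure_gradient(self, p):
        px, py, pz = self._face_pressures(p)
        wx, wy, wz = self._cell_widths
        return ((px[1:] - px[:-1]) / wx,
                (py[:, 1:] - py[:, :-1]) / wy,
                (pz[:, :, 1:] - pz[:, :, :-1]) / wz)

    # ------------------------------------------------------------------
    def _momentum(self, mu_eff):
        """Assemble and solve the three momentum equations; returns
        (residuals, ap_simplec per component)."""
        st, bc, props = self.settings, self.bc, self.props
        rho = props.rho_ref
        Dx, Dy, Dz = self._face_diffusion(mu_eff)
        ap0, aW, aE, aS, aN, aB, aT = _upwind_coeffs(self.disc, self.Fx, self.Fy, self.Fz, Dx, Dy, Dz)
        anb_sum = aW + aE + aS + aN + aB + aT

        dpdx, dpdy, dpdz = self._pressure_gradient(self.p)
        rho_T = props.rho(self.T)
        # rho(T) < rho_ref where hot -> positive (upward) buoyancy source
        buoy = (rho - rho_T) * GRAVITY * self.V

        results = {}
        ap_simplec = {}
        resid = {}
        self._ap_rc = {}
        axes = {"u": (0, self.u, dpdx), "v": (1, self.v, dpdy), "w": (2, self.w, dpdz)}
        # wall-shear coefficients per boundary side (tangential components)
        wall_cw = {}
        for (ax, side), mask in self.any_wall.items():
            axis = "xyz".index(ax)
            y = self.disc.halfw[axis]
            cw = _wall_coefficient(self.k, y, props, self.const)
            wall_cw[(ax, side)] = (mask, cw * self.disc.A[axis])

        for name, (axis, phi, dpd) in axes.items():
            ap = ap0.copy()
            b = -dpd * self.V + self._deferred_central(phi)
            if name == "w":
                b = b + buoy
            # inlet: Dirichlet (0, 0, -V_in)
            phi_in = -bc.inlet_velocity if name == "w" else 0.0
            for (ax, side), mask in self.inlet_cells.items():
                a = "xyz".index(ax)
                Dpatch = mu_eff[mask] * self.disc.A[a][mask] / self.disc.halfw[a][mask]
                Fin = rho * bc.inlet_velocity * self.disc.A[a][mask]
                # boundary face: diffusion in ap, inflow convection in b only
                ap[mask] += Dpatch
                b[mask] += (Dpatch + Fin) * phi_in
            # outlet: outflow (upwind), reversed flow brings quiescent air
            for (ax, side), mask in self.outlet_cells.items():
                Fout = self._outlet_face_flux(ax, side)[mask]
                ap[mask] += np.maximum(Fout, 0.0)
                # inflow brings phi = 0 -> no b term for velocity
            # walls: shear on tangential components via wall functions
            for (ax, side), (mask, cwA) in wall_cw.items():
                a = "xyz".index(ax)
                if a == axis:
                    continue  # normal component: impermeable, no shear link
                ap[mask] += cwA[mask]
            # source cell: injected mass carries its own (vertical) velocity;
            # the matching mass sink is already in ap through the face fluxes
            # (continuity gives the cell a net outflow of mdot)
            if self.src is not None and name == "w":
                b[self.src.cell] += self.src.mdot * self.src.w_injection
            # pseudo-transient inertia (cancels at steady state)
            pseudo = rho * self.V / st.pseudo_dt
            ap = ap + pseudo
            b = b + pseudo * phi
            ap_unrelaxed = ap.copy()
            # implicit under-relaxation
            ap = ap / st.relax_momentum
            b = b + (ap - ap_unrelaxed) * phi
            _mask_solid(ap, aW, aE, aS, aN, aB, aT, b, self.disc.fluid)
            self._scales[name] = float(np.abs(ap_unrelaxed * phi)[self.disc.fluid].sum())
            resid[name] = _residual(ap_unrelaxed, aW, aE, aS, aN, aB, aT,
                                    b - (ap - ap_unrelaxed) * phi, phi,
                                    self.disc.fluid)
            _rb_gs(ap, aW, aE, aS, aN, aB, aT, b, phi, 6)
            phi[self.disc.solid] = 0.0
            self._ap_rc[name] = self.V / ap
            # SIMPLEC denominator (relaxed ap minus neighbour sum)
            denom = np.maximum(ap - anb_sum, 1e-30)
            ap_simplec[name] = self.V / denom
            results[name] = phi
        return resid, ap_simplec

    def A_for(self, axis: int) -> np.ndarray:
        """Per-cell boundary-face area along one axis (broadcast array)."""
        return self.disc.A[axis]

    def _deferred_central(self, phi) -> np.ndarray:
        """Deferred-correction source that moves the implicit upwind
        convection toward central differencing on interior faces."""
        lam = self.settings.central_blend
        b = np.zeros(self.mesh.n)
        if lam == 0.0:
            return b
        # x faces
        F = self.Fx[1:-1]
        up = np.where(F > 0, phi[:-1], phi[1:])
        corr = lam * F * (up - 0.5 * (phi[:-1] + phi[1:]))
        corr[~self.disc.int_x] = 0.0
        b[:-1] += corr
        b[1:] -= corr
        # y faces
        F = self.Fy[:, 1:-1]
        up = np.where(F > 0, phi[:, :-1], phi[:, 1:])
        corr = lam * F * (up - 0.5 * (phi[:, :-1] + phi[:, 1:]))
        corr[~self.disc.int_y] = 0.0
        b[:, :-1] += corr
        b[:, 1:] -= corr
        # z faces
        F = self.Fz[:, :, 1:-1]
        up = np.where(F > 0, phi[:, :, :-1], phi[:, :, 1:])
        corr = lam * F * (up - 0.5 * (phi[:, :, :-1] + phi[:, :, 1:]))
        corr[~self.disc.int_z] = 0.0
        b[:, :, :-1] += corr
        b[:, :, 1:] -= corr
        return b

    def _outlet_face_flux(self, ax: str, side: int) -> np.ndarray:
        """Outward mass flux (kg/s) through the outlet face of each cell
        (zero where the cell has no outlet face on that side)."""
        mesh = self.mesh
        out = np.zeros(mesh.n)
        if ax == "y" and side == 0:
            m = mesh.fy[:, 0] == Patch.OUTLET
            out[:, 0, :][m] = -self.Fy[:, 0][m]
        elif ax == "y" and side == 1:
            m = mesh.fy[:, -1] == Patch.OUTLET
            out[:, -1, :][m] = self.Fy[:, -1][m]
        return out

    # ------------------------------------------------------------------
    def _update_fluxes(self, ap_simplec):
        """Rhie-Chow face velocities -> face mass fluxes (interior faces),
        outlet fluxes from adjacent cell velocity, inlet fluxes fixed."""
        mesh, rho = self.mesh, self.props.rho_ref
        dpdx, dpdy, dpdz = self._pressure_gradient(self.p)
        dV = self._ap_rc   # V/ap for the Rhie-Chow dissipation term
        dcx, dcy, dcz = self._interior_deltas
        Axf, Ayf, Azf = self._face_area_arrays
        ix, iy, iz = self.disc.int_x, self.disc.int_y, self.disc.int_z

        uf = 0.5 * (self.u[1:] + self.u[:-1]) \
            + 0.5 * (dV["u"][1:] + dV["u"][:-1]) \
            * (0.5 * (dpdx[1:] + dpdx[:-1]) - (self.p[1:] - self.p[:-1]) / dcx)
        Fxf = rho * uf * Axf
        self.Fx[1:-1][ix] = Fxf[ix]
        self.Fx[1:-1][~ix] = 0.0
        self.Fx[0] = 0.0
        self.Fx[-1] = 0.0

        vf = 0.5 * (self.v[:, 1:] + self.v[:, :-1]) \
            + 0.5 * (dV["v"][:, 1:] + dV["v"][:, :-1]) \
            * (0.5 * (dpdy[:, 1:] + dpdy[:, :-1]) - (self.p[:, 1:] - self.p[:, :-1]) / dcy)
        Fyf = rho * vf * Ayf
        self.Fy[:, 1:-1][iy] = Fyf[iy]
        self.Fy[:, 1:-1][~iy] = 0.0
        # outlet faces: take cell velocity (zero-gradient outflow)
        Ay_face = mesh.face_areas(1)
        m0 = mesh.fy[:, 0] == Patch.OUTLET
        self.Fy[:, 0] = 0.0
        self.Fy[:, 0][m0] = rho * self.v[:, 0][m0] * Ay_face[m0]
        m1 = mesh.fy[:, -1] == Patch.OUTLET
        self.Fy[:, -1] = 0.0
        self.Fy[:, -1][m1] = rho * self.v[:, -1][m1] * Ay_face[m1]

        wf = 0.5 * (self.w[:, :, 1:] + self.w[:, :, :-1]) \
            + 0.5 * (dV["w"][:, :, 1:] + dV["w"][:, :, :-1]) \
            * (0.5 * (dpdz[:, :, 1:] + dpdz[:, :, :-1]) - (self.p[:, :, 1:] - self.p[:, :, :-1]) / dcz)
        Fzf = rho * wf * Azf
        self.Fz[:, :, 1:-1][iz] = Fzf[iz]
        self.Fz[:, :, 1:-1][~iz] = 0.0
        self.Fz[:, :, 0] = 0.0
        top = np.zeros(self.Fz[:, :, -1].shape)
        Az_face = mesh.face_areas(2)
        top[self.inlet_flux_faces] = -rho * self.bc.inlet_velocity * Az_face[self.inlet_flux_faces]
        self.Fz[:, :, -1] = top

    def _continuity_imbalance(self) -> np.ndarray:
        """Net outflow minus sources per cell (kg/s)."""
        out = (self.Fx[1:] - self.Fx[:-1]
               + self.Fy[:, 1:] - self.Fy[:, :-1]
               + self.Fz[:, :, 1:] - self.Fz[:, :, :-1])
        if self.src is not None:
            out[self.src.cell] -= self.src.mdot
        out[self.disc.solid] = 0.0
        return out

    def _pressure_correction(self, ap_simplec):
        mesh, rho = self.mesh, self.props.rho_ref
        nx, ny, nz = mesh.n
        dcx, dcy, dcz = self._interior_deltas
        Axf, Ayf, Azf = self._face_area_arrays
        dfx = np.zeros((nx + 1, ny, nz))
        dfy = np.zeros((nx, ny + 1, nz))
        dfz = np.zeros((nx, ny, nz + 1))
        dfx[1:-1][self.disc.int_x] = (0.5 * (ap_simplec["u"][1:] + ap_simplec["u"][:-1])
                                      * rho * Axf / dcx)[self.disc.int_x]
        dfy[:, 1:-1][self.disc.int_y] = (0.5 * (ap_simplec["v"][:, 1:] + ap_simplec["v"][:, :-1])
                                         * rho * Ayf / dcy)[self.disc.int_y]
        dfz[:, :, 1:-1][self.disc.int_z] = (0.5 * (ap_simplec["w"][:, :, 1:] + ap_simplec["w"][:, :, :-1])
                                            * rho * Azf / dcz)[self.disc.int_z]
        aW, aE = dfx[:-1], dfx[1:]
        aS, aN = dfy[:, :-1], dfy[:, 1:]
        aB, aT = dfz[:, :, :-1], dfz[:, :, 1:]
        ap = aW + aE + aS + aN + aB + aT
        # outlet faces: p' = 0 at the face (half-cell link)
        Ay_face = mesh.face_areas(1)
        wy = mesh.widths(1)
        out_coeff = np.zeros(mesh.n)
        m0 = mesh.fy[:, 0] == Patch.OUTLET
        out_coeff[:, 0, :][m0] = ap_simplec["v"][:, 0][m0] * rho \
            * Ay_face[m0] / (wy[0] / 2.0)
        m1 = mesh.fy[:, -1] == Patch.OUTLET
        out_coeff[:, -1, :][m1] = ap_simplec["v"][:, -1][m1] * rho \
            * Ay_face[m1] / (wy[-1] / 2.0)
        ap = ap + out_coeff
        imbalance = self._continuity_imbalance()
        b = -imbalance
        aWc, aEc, aSc, aNc, aBc, aTc = (x.copy() for x in (aW, aE, aS, aN, aB, aT))
        apc = ap.copy()
        _mask_solid(apc, aWc, aEc, aSc, aNc, aBc, aTc, b, self.disc.fluid)
        apc[apc == 0] = 1.0
        pprime = _cg_stencil(apc, aWc, aEc, aSc, aNc, aBc, aTc, b,
                             rtol=self._pressure_rtol, maxiter=4000)
        pprime[self.disc.solid] = 0.0

        # flux corrections (exact per-face, conserves mass cell-wise)
        self.Fx[1:-1] += dfx[1:-1] * (pprime[:-1] - pprime[1:])
        self.Fy[:, 1:-1] += dfy[:, 1:-1] * (pprime[:, :-1] - pprime[:, 1:])
        self.Fz[:, :, 1:-1] += dfz[:, :, 1:-1] * (pprime[:, :, :-1] - pprime[:, :, 1:])
        self.Fy[:, 0][m0] -= out_coeff[:, 0, :][m0] * pprime[:, 0, :][m0]
        self.Fy[:, -1][m1] += out_coeff[:, -1, :][m1] * pprime[:, -1, :][m1]

        # velocity corrections from p' gradient
        gpx, gpy, gpz = self._pprime_gradient(pprime, m0, m1)
        self.u -= ap_simplec["u"] * gpx
        self.v -= ap_simplec["v"] * gpy
        self.w -= ap_simplec["w"] * gpz
        for a in (self.u, self.v, self.w):
            a[self.disc.solid] = 0.0
        self.p += self.settings.relax_pressure * pprime
        return float(np.abs(imbalance[self.disc.fluid]).sum())

    def _pprime_gradient(self, pprime, m0, m1):
        mesh = self.mesh
        nx, ny, nz = mesh.n
        px = np.zeros((nx + 1, ny, nz))
        py = np.zeros((nx, ny + 1, nz))
        pz = np.zeros((nx, ny, nz + 1))
        px[1:-1] = 0.5 * (pprime[1:] + pprime[:-1])
        py[:, 1:-1] = 0.5 * (pprime[:, 1:] + pprime[:, :-1])
        pz[:, :, 1:-1] = 0.5 * (pprime[:, :, 1:] + pprime[:, :, :-1])
        px[0], px[-1] = pprime[0], pprime[-1]
        py[:, 0], py[:, -1] = pprime[:, 0], pprime[:, -1]
        pz[:, :, 0], pz[:, :, -1] = pprime[:, :, 0], pprime[:, :, -1]
        py[:, 0][m0] = 0.0
        py[:, -1][m1] = 0.0
        wx, wy, wz = self._cell_widths
        return ((px[1:] - px[:-1]) / wx,
                (py[:, 1:] - py[:, :-1]) / wy,
                (pz[:, :, 1:] - pz[:, :, :-1]) / wz)

    # ------------------------------------------------------------------
    def _scalar(self, phi, gamma, extra_ap, extra_b, relax, inlet_value,
                fix_mask=None, fix_value=None, outlet_inflow_value=0.0,
                central=False):
        """Assemble/solve one scalar conv-diff equation; returns residual."""
        bc, rho = self.bc, self.props.rho_ref
        Dx, Dy, Dz = self._face_diffusion(gamma)
        ap, aW, aE, aS, aN, aB, aT = _upwind_coeffs(self.disc, self.Fx, self.Fy, self.Fz, Dx, Dy, Dz)
        b = extra_b.copy()
        if central:
            b += self._deferred_central(phi)
        ap = ap + extra_ap
        for (ax, side), mask in self.inlet_cells.items():
            a = "xyz".index(ax)
            Dpatch = gamma[mask] * self.disc.A[a][mask] / self.disc.halfw[a][mask]
            Fin = rho * bc.inlet_velocity * self.disc.A[a][mask]
            ap[mask] += Dpatch
            b[mask] += (Dpatch + Fin) * inlet_value
        for (ax, side), mask in self.outlet_cells.items():
            Fout = self._outlet_face_flux(ax, side)[mask]
            ap[mask] += np.maximum(Fout, 0.0)
            b[mask] += np.maximum(-Fout, 0.0) * outlet_inflow_value
        # pseudo-transient inertia, as in momentum
        pseudo = rho * self.V / self.settings.pseudo_dt
        ap = ap + pseudo
        b = b + pseudo * phi
        if fix_mask is not None:
            for arr in (aW, aE, aS, aN, aB, aT):
                arr[fix_mask] = 0.0
            ap[fix_mask] = 1.0
            b[fix_mask] = fix_value[fix_mask]
        ap_unrelaxed = ap.copy()
        ap = ap / relax
        b = b + (ap - ap_unrelaxed) * phi
        _mask_solid(ap, aW, aE, aS, aN, aB, aT, b, self.disc.fluid)
        scale = float(np.abs(ap_unrelaxed * phi)[self.disc.fluid].sum())
        res = _residual(ap_unrelaxed, aW, aE, aS, aN, aB, aT,
                        b - (ap - ap_unrelaxed) * phi, phi, self.disc.fluid)
        _rb_gs(ap, aW, aE, aS, aN, aB, aT, b, phi, 4)
        return res, scale

    def _energy(self, mu_t):
        props, const, st = self.props, self.const, self.settings
        gamma = props.mu / const.sigma_T + mu_t / const.sigma_tT
        extra_ap = np.zeros(self.mesh.n)
        extra_b = np.zeros(self.mesh.n)
        # Robin side walls: exterior transfer coefficient in series with the
        # interior film conductance (effective diffusivity across the half
        # cell), i.e. q = U (T_ext - T_cell), 1/U = 1/h + 1/h_int.  The
        # T-equation carries q A / cp (units kg K/s).
        for (ax, side), mask in self.wall_cells[Patch.SIDEWALL].items():
            a = "xyz".index(ax)
            h_int = props.cp * gamma[mask] / self.disc.halfw[a][mask]
            U = 1.0 / (1.0 / self.bc.wall_htc + 1.0 / np.maximum(h_int, 1e-12))
            coeff = U * self.disc.A[a][mask] / props.cp
            extra_ap[mask] += coeff
            extra_b[mask] += coeff * self.T_ext
        if self.src is not None:
            # injected enthalpy; the outgoing mdot*T_P sink is carried by the
            # net face outflow of the source cell
            extra_b[self.src.cell] += self.src.mdot * self.src.temperature
        res, self._scales["T"] = self._scalar(
            self.T, gamma, extra_ap, extra_b, st.relax_scalar,
            self.T_in, outlet_inflow_value=self.T_in, central=True)
        lo = min(self.T_in, self.T_ext) - 5.0
        hi = max(self.T_ext, self.src.temperature if self.src else self.T_in)
        np.clip(self.T, lo, hi, out=self.T)
        self.T[self.disc.solid] = self.T_in
        return res

    def _turbulence(self, mu_eff, mu_t):
        props, const, st = self.props, self.const, self.settings
        rho = props.rho_ref
        coords = tuple(self.mesh.centers(a) for a in range(3))
        Gk = production_Gk(self.u, self.v, self.w, coords, mu_t)
        Gk[self.disc.solid] = 0.0
        # near-wall equilibrium dissipation (fixed in wall-adjacent cells)
        eps_wall = np.zeros(self.mesh.n)
        wall_mask = np.zeros(self.mesh.n, dtype=bool)
        for (ax, side), mask in self.any_wall.items():
            a = "xyz".index(ax)
            y = self.disc.halfw[a]
            val = const.Cmu ** 0.75 * np.maximum(self.k, 1e-14) ** 1.5 / (VON_KARMAN * y)
            newly = mask & ~wall_mask
            eps_wall[newly] = val[newly]
            # if multiple walls, keep the larger dissipation (smallest y)
            both = mask & wall_mask
            eps_wall[both] = np.maximum(eps_wall[both], val[both])
            wall_mask |= mask

        # k equation
        gamma_k = mu_eff / const.sigma_k
        extra_ap = rho * self.eps / np.maximum(self.k, 1e-14) * self.V
        extra_b = Gk * self.V
        res_k, self._scales["k"] = self._scalar(
            self.k, gamma_k, extra_ap, extra_b, st.relax_scalar, self.k_in)
        np.clip(self.k, 1e-14, None, out=self.k)

        # eps equation
        gamma_e = mu_eff / const.sigma_eps
        ratio = self.eps / np.maximum(self.k, 1e-14)
        extra_ap = const.C2 * rho * ratio * self.V
        extra_b = const.C1 * ratio * Gk * self.V
        res_e, self._scales["eps"] = self._scalar(
            self.eps, gamma_e, extra_ap, extra_b, st.relax_scalar, self.eps_in,
            fix_mask=wall_mask, fix_value=eps_wall)
        np.clip(self.eps, 1e-16, None, out=self.eps)
        return res_k, res_e

    # ------------------------------------------------------------------
    def iterate(self) -> dict[str, float]:
        const, props = self.const, self.props
        self._scales = {}
        mu_eff = effective_viscosity(self.k, self.eps, props, const)
        mu_t = mu_eff - props.mu
        resid, ap_simplec = self._momentum(mu_eff)
        self._ap_simplec = ap_simplec
        self._update_fluxes(ap_simplec)
        mass_res = self._pressure_correction(ap_simplec)
        res_k, res_e = self._turbulence(mu_eff, mu_t)
        res_T = self._energy(mu_t)
        resid.update({"mass": mass_res, "k": res_k, "eps": res_e, "T": res_T})
        return resid

    def solve(self) -> FieldState:
        st = self.settings
        history: dict[str, list[float]] = {}
        norms: dict[str, float] = {}
        converged = False
        for it in range(st.max_iterations):
            resid = self.iterate()
            # scaled residuals: each equation's imbalance against the
            # magnitude of its own transport terms (sum |ap phi|), floored
            # by a characteristic throughput so trivially satisfied
            # equations read as converged rather than 0/0
            floors = {
                "u": self.mdot_in * self.bc.inlet_velocity,
                "v": self.mdot_in * self.bc.inlet_velocity,
                "w": self.mdot_in * self.bc.inlet_velocity,
                "k": self.mdot_in * self.k_in,
                "eps": self.mdot_in * self.eps_in,
                "T": self.mdot_in * self.T_in,
                "mass": self.mdot_in,
            }
            norms = {key: max(self._scales.get(key, 0.0), floors[key])
                     for key in resid}
            scaled = {k: v / norms[k] for k, v in resid.items()}
            for k, v in scaled.items():
                history.setdefault(k, []).append(v)
            if any(not math.isfinite(v) for v in resid.values()) or \
                    max(abs(self.u).max(), abs(self.v).max(),
                        abs(self.w).max()) > st.velocity_bound:
                raise SolverFault(f"solver diverged at iteration {it}", history=history)
            if it + 1 >= st.min_iterations and max(scaled.values()) < st.tolerance:
                converged = True
                break
        # polish continuity, then transport the passive scalars
        self._polish_continuity()
        state = FieldState(
            mesh=self.mesh, u=self.u, v=self.v, w=self.w, p=self.p, T=self.T,
            k=self.k, eps=self.eps, converged=converged,
            residual_history=history, fluxes=(self.Fx, self.Fy, self.Fz),
            source=self.src, bc=self.bc)
        self._transport_species(state)
        return state

    def _polish_continuity(self, rounds: int = 3):
        """A few extra tight pressure projections at frozen momentum so the
        face fluxes used by the passive scalars conserve mass tightly."""
        self._pressure_rtol = 1e-10
        for _ in range(rounds):
            self._pressure_correction(self._ap_simplec)

    # ------------------------------------------------------------------
    def _transport_species(self, state: FieldState):
        """Steady passive transport of waste-gas species and dispersed
        phases on the converged flux field (direct linear solves)."""
        props, const = self.props, self.const
        mu_eff = effective_viscosity(self.k, self.eps, props, const)
        mu_t = mu_eff - props.mu
        gamma = props.mu / const.sigma_T + mu_t / const.sigma_tT
        if self.src is None:
            zero = np.zeros(self.mesh.n)
            state.species = {s: zero.copy() for s in self.SPECIES}
            state.c_tar = zero.copy()
            state.c_particle = zero.copy()
            return
        rho_T = props.rho(self.T)
        for name in self.SPECIES:
            y_src = self.src.species_mass_fractions.get(name, 0.0)
            state.species[name] = self._passive(gamma, self.src.mdot * y_src)
        y_tar = self._passive(gamma, self.src.tar_rate)
        y_par = self._passive(gamma, self.src.particle_rate)
        state.c_tar = y_tar * rho_T * 1e3        # g/m^3
        state.c_particle = y_par * rho_T * 1e3

    def _passive(self, gamma, injection_rate: float) -> np.ndarray:
        """Solve one steady passive-scalar equation with a point source
        injecting ``injection_rate`` kg/s; returns the mass-fraction field."""
        rho, bc = self.props.rho_ref, self.bc
        Dx, Dy, Dz = self._face_diffusion(gamma)
        ap, aW, aE, aS, aN, aB, aT = _upwind_coeffs(self.disc, self.Fx, self.Fy, self.Fz, Dx, Dy, Dz)
        b = np.zeros(self.mesh.n)
        # inflow boundary: pure convection with Y = 0 (no upstream diffusion
        # against the incoming stream -- the boundary-layer Peclet number is
        # far above 1, and a Dirichlet half-cell diffusion link would leak
        # species mass out through the inlet); nothing to add to ap or b.
        for (ax, side), mask in self.outlet_cells.items():
            Fout = self._outlet_face_flux(ax, side)[mask]
            ap[mask] += np.maximum(Fout, 0.0)
        b[self.src.cell] += injection_rate
        _mask_solid(ap, aW, aE, aS, aN, aB, aT, b, self.disc.fluid)
        phi = _solve_direct(ap, aW, aE, aS, aN, aB, aT, b)
        phi[self.disc.solid] = 0.0
        return np.maximum(phi, 0.0)


def solve_steady(mesh: Mesh, bc: BoundaryConditionSet,
                 source: SourceSpec | SourceTerms | None,
                 settings: SolverSettings | None = None,
                 constants: TurbulenceConstants | None = None,
                 props: GasProperties | None = None) -> FieldState:
    """Run the SIMPLEC outer iteration to steady state.

    ``source`` may be a :class:`~theatresmoke.empirical.SourceSpec` (it is
    converted with :func:`assemble_source`), pre-assembled
    :class:`SourceTerms`, or None for an unforced room.
    """
    props = props or GasProperties()
    if isinstance(source, SourceSpec):
        source = assemble_source(source, mesh, props)
    solver = RansSolver(mesh, bc, source, settings, constants, props)
    return solver.solve()


def mass_balance(state: FieldState) -> dict[str, float]:
    """Global mass audit from the converged face fluxes (kg/s)."""
    mesh = state.mesh
    Fx, Fy, Fz = state.fluxes
    inlet = -Fz[:, :, -1][mesh.fz[:, :, -1] == Patch.INLET].sum()
    out0 = -Fy[:, 0][mesh.fy[:, 0] == Patch.OUTLET].sum()
    out1 = Fy[:, -1][mesh.fy[:, -1] == Patch.OUTLET].sum()
    src = state.source.mdot if state.source else 0.0
    return {
        "inlet": float(inlet), "outlet": float(out0 + out1), "source": float(src),
        "imbalance": float(inlet + src - (out0 + out1)),
        "relative_imbalance": float(abs(inlet + src - (out0 + out1)) / max(inlet, 1e-300)),
    }


def species_balance(state: FieldState, name: str | None = None) -> dict[str, float]:
    """Audit one passive scalar: outlet mass flux vs injection (kg/s)."""
    mesh = state.mesh
    Fx, Fy, Fz = state.fluxes
    src = state.source
    if name is None or name in ("tar", "particle"):
        rho_T = GasProperties().rho(state.T)
        if name == "particle":
            y = state.c_particle / (rho_T * 1e3)
            inj = src.particle_rate
        else:
            y = state.c_tar / (rho_T * 1e3)
            inj = src.tar_rate
    else:
        y = state.species[name]
        inj = src.mdot * src.species_mass_fractions.get(name, 0.0)
    m0 = mesh.fy[:, 0] == Patch.OUTLET
    m1 = mesh.fy[:, -1] == Patch.OUTLET
    out = (-Fy[:, 0][m0] * y[:, 0, :][m0]).sum() + (Fy[:, -1][m1] * y[:, -1, :][m1]).sum()
    return {"injection": float(inj), "outlet": float(out),
            "relative_imbalance": float(abs(inj - out) / max(inj, 1e-300))}


# ---------------------------------------------------------------------------
# 1-D verification sub-solver

def solve_conv_diff_1d(n: int, length: float, rho_u: float, gamma: float,
                       phi_left: float, phi_right: float) -> tuple[np.ndarray, np.ndarray]:
    """First-order-upwind/central 1-D steady advection-diffusion solve.

    The same face-based coefficients as the 3-D solver, on an ``n``-cell
    uniform grid with Dirichlet ends.  Returns (cell centres, phi).  The
    exact solution is (exp(Pe x/L) - 1)/(exp(Pe) - 1) scaled between the
    end values; agreement verifies the discrete operator.
    """
    dx = length / n
    D = gamma / dx
    F = rho_u
    aW = np.full(n, D + max(F, 0.0))
    aE = np.full(n, D + max(-F, 0.0))
    ap = aW + aE
    b = np.zeros(n)
    # Dirichlet ends: half-cell diffusion plus upwind convection
    Db = gamma / (dx / 2.0)
    aW[0] = 0.0
    ap[0] = aE[0] + Db + max(F, 0.0)
    b[0] = (Db + max(F, 0.0)) * phi_left
    aE[-1] = 0.0
    ap[-1] = aW[-1] + Db + max(-F, 0.0)
    b[-1] = (Db + max(-F, 0.0)) * phi_right
    A = sp.diags([-aW[1:], ap, -aE[:-1]], offsets=[-1, 0, 1], format="csc")
    phi = spla.spsolve(A, b)
    x = (np.arange(n) + 0.5) * dx
    return x, phi
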