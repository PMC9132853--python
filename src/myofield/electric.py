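"""Coupled multi-domain electric solver.

Solves, on the structured tissue grid, the quasi-static system

* elliptic balance for the extracellular/body potential:
  ``0 = div[σ_e grad φ_e] + Σ_k f_r^k div[σ_i^k grad(V_m^k + φ_e)]`` in the
  muscle and ``div[σ_b grad φ_b] = 0`` in the fat slab, with a single shared
  unknown at the interface (potential continuity + conservative flux via
  harmonic face averaging), zero-Neumann outer boundaries, and one grounded
  node pinning the otherwise one-dimensional nullspace;
* per-unit transmembrane diffusion
  ``∂V_m/∂t = [div σ_i grad(V_m + φ_e) − A_m I_ion]/(C_m A_m)``, which with a
  fibre-aligned rank-one σ_i is independent 1-D diffusion along each fibre
  line (backward Euler, zero intracellular flux at fibre ends);
* pointwise membrane reaction kinetics (delegated to :mod:`.membrane`).

Time integration is Godunov splitting: reaction substeps, elliptic solve,
implicit diffusion.  The elliptic operator is time-invariant and factorised
once per run.  Units: mV, ms, cm, mS/cm, µA/cm².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import membrane as mb
from .geometry import (
    ConductivityModel,
    ConfigurationError,
    MotorUnitMap,
    SimulationGrid,
)


class SolverError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# elliptic operator
# ---------------------------------------------------------------------------


def _axis_conductivities(grid: SimulationGrid, cond: ConductivityModel) -> np.ndarray:
    """Per-node diagonal conductivity of the φ operator over the tissue box.

    Muscle nodes carry σ_e + Σ_k f_r^k σ_i^k (= σ_e + σ_i, the recruitment
    densities partition the muscle); body nodes the isotropic σ_b.
    """
    nx, ny, nz = grid.shape
    sig = np.empty((nx, ny, nz, 3))
    nz_m = grid.n_muscle_z
    sig[:, :, :nz_m, :] = cond.combined_muscle()
    sig[:, :, nz_m:, :] = cond.sigma_b
    return sig


def _face_weights(sig_ax: np.ndarray, spacing, axis: int) -> np.ndarray:
    """Harmonic-mean face conductivity / h² between axis-neighbours."""
    a = np.moveaxis(sig_ax[..., axis], axis, 0)
    lo, hi = a[:-1], a[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        face = np.where(lo + hi > 0, 2.0 * lo * hi / (lo + hi), 0.0)
    return np.moveaxis(face, 0, axis) / spacing[axis] ** 2


@dataclass(frozen=True)
class EllipticOperator:
    """Assembled φ operator ``L = div σ grad`` with one pinned node."""

    matrix: sp.csc_matrix          # symmetric, pinned
    grid: SimulationGrid
    ground_index: int              # flat index of the grounded node

    def factorise(self):
        return spla.splu(self.matrix.tocsc())


def _ground_node(grid: SimulationGrid, motor_units: MotorUnitMap | None) -> int:
    """Corner of the conductive box farthest from the recruited fibre line."""
    nx, ny, nz = grid.shape
    if motor_units is None:
        return 0
    iy0, iz0 = motor_units.mu1_line
    best, best_d = 0, -1.0
    for iy in (0, ny - 1):
        for iz in (0, nz - 1):
            d = (iy - iy0) ** 2 + (iz - iz0) ** 2
            if d > best_d:
                best_d, best = d, np.ravel_multi_index((0, iy, iz), grid.shape)
    return int(best)


def assemble_elliptic_operator(
    grid: SimulationGrid,
    cond: ConductivityModel,
    motor_units: MotorUnitMap | None = None,
    pin: bool = True,
) -> EllipticOperator:
    """Build the symmetric 7-point operator over all conductive nodes.

    Before pinning, the operator has zero row sums (pure-Neumann closure);
    pinning replaces the grounded node's row and column by the identity.
    """
    nx, ny, nz = grid.shape
    n = nx * ny * nz
    sig = _axis_conductivities(grid, cond)
    if not np.isfinite(sig).all():
        raise ConfigurationError("non-finite conductivities")

    rows, cols, vals = [], [], []
    diag = np.zeros((nx, ny, nz))
    idx = np.arange(n).reshape(nx, ny, nz)
    for axis in range(3):
        w = _face_weights(sig, grid.spacing, axis)
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(0, -1)
        sl_hi[axis] = slice(1, None)
        i_lo = idx[tuple(sl_lo)].ravel()
        i_hi = idx[tuple(sl_hi)].ravel()
        wf = w.ravel()
        rows.extend((i_lo, i_hi))
        cols.extend((i_hi, i_lo))
        vals.extend((wf, wf))
        np.add.at(diag.reshape(-1), i_lo, -wf)
        np.add.at(diag.reshape(-1), i_hi, -wf)
    rows.append(idx.ravel())
    cols.append(idx.ravel())
    vals.append(diag.ravel())
    L = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()

    # connectivity sanity: every node must couple to a neighbour
    if np.any(diag == 0):
        raise ConfigurationError("disconnected conductive region (zero-coupled node)")

    g = _ground_node(grid, motor_units)
    if pin:
        L = L.tolil()
        L[g, :] = 0.0
        L[:, g] = 0.0
        L[g, g] = 1.0
        L = L.tocsc()
    return EllipticOperator(matrix=L.tocsc(), grid=grid, ground_index=g)


# ---------------------------------------------------------------------------
# 1-D fibre-line diffusion
# ---------------------------------------------------------------------------


def _d2_neumann(nx: int, h: float) -> sp.csr_matrix:
    """1-D div-grad with zero-flux ends (mirror closure), 1/cm² scaling."""
    main = np.full(nx, -2.0)
    main[0] = main[-1] = -1.0
    off = np.ones(nx - 1)
    return sp.diags([off, main, off], [-1, 0, 1]).tocsr() / h**2


@dataclass
class FibreDiffusion:
    """Backward-Euler operator for V_m diffusion along fibre lines.

    All fibre lines share the same tridiagonal matrix
    ``M = I − dt·D·D2`` with diffusivity ``D = σ_i_l/(C_m A_m)`` (cm²/ms),
    factorised once (banded Cholesky) and applied to every line per step.
    """

    d2: sp.csr_matrix
    cho: np.ndarray
    coef: float  # dt * D

    @classmethod
    def build(cls, nx: int, h: float, sigma_i_l: float, c_m: float, a_m: float,
              dt: float) -> "FibreDiffusion":
        d2 = _d2_neumann(nx, h)
        coef = dt * sigma_i_l / (c_m * a_m)
        m = (sp.eye(nx) - coef * d2).toarray()
        ab = np.zeros((2, nx))
        ab[0, 1:] = np.diag(m, 1)
        ab[1, :] = np.diag(m)
        cho = scipy.linalg.cholesky_banded(ab, lower=False)
        return cls(d2=d2, cho=cho, coef=coef)

    def step(self, v_lines: np.ndarray, phi_lines: np.ndarray) -> np.ndarray:
        """One implicit step; arrays are (nx, n_lines)."""
        rhs = v_lines + self.coef * (self.d2 @ phi_lines)
        return scipy.linalg.cho_solve_banded((self.cho, False), rhs)


def diffuse_vm(
    state: mb.MembraneState,
    phi_e: np.ndarray,
    diffusion: FibreDiffusion,
) -> mb.MembraneState:
    """Implicit transmembrane diffusion along the fibre axis, per unit.

    ``phi_e`` is the extracellular potential on the muscle box; the
    intracellular flux closure applies zero-Neumann to V_m + φ_e jointly.
    """
    n_units = state.v_m.shape[0]
    nx = state.v_m.shape[1]
    phi_flat = phi_e.reshape(nx, -1)
    for k in range(n_units):
        v = state.v_m[k].reshape(nx, -1)
        state.v_m[k] = diffusion.step(v, phi_flat).reshape(state.v_m[k].shape)
    return state


# ---------------------------------------------------------------------------
# elliptic solve
# ---------------------------------------------------------------------------


def membrane_source(
    state: mb.MembraneState,
    motor_units: MotorUnitMap,
    sigma_i_l: float,
    grid: SimulationGrid,
) -> np.ndarray:
    """RHS of the φ equation: ``−Σ_k f_r^k div[σ_i grad V_m^k]`` on the box."""
    nx, ny, nz = grid.shape
    h = grid.spacing[0]
    rhs_m = np.zeros(grid.muscle_shape)
    for k in range(motor_units.n_units):
        v = state.v_m[k]
        d2 = np.empty_like(v)
        d2[1:-1] = v[:-2] - 2.0 * v[1:-1] + v[2:]
        d2[0] = v[1] - v[0]
        d2[-1] = v[-2] - v[-1]
        rhs_m -= motor_units.f_r[k] * sigma_i_l * d2 / h**2
    rhs = np.zeros((nx, ny, nz))
    rhs[:, :, : grid.n_muscle_z] = rhs_m
    return rhs


def solve_extracellular(
    lu,
    operator: EllipticOperator,
    state: mb.MembraneState,
    motor_units: MotorUnitMap,
    sigma_i_l: float,
) -> np.ndarray:
    """Solve the pinned elliptic system for φ over the tissue box (mV)."""
    grid = operator.grid
    rhs = membrane_source(state, motor_units, sigma_i_l, grid).ravel()
    rhs[operator.ground_index] = 0.0
    phi = lu.solve(rhs)
    if not np.isfinite(phi).all():
        res = np.linalg.norm(operator.matrix @ phi - rhs)
        raise SolverError(f"elliptic solve failed (residual {res:.3e})")
    return phi.reshape(grid.shape)


# ---------------------------------------------------------------------------
# current densities
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CurrentDensityField:
    """Domain-wise conduction current densities (µA/cm²) at one instant.

    ``j_i`` is per representative fibre-matrix cylinder; weight by the
    recruitment density ``f_r`` when superposing domains (magnetics).
    """

    j_e: np.ndarray   # (nx, ny, nz_m, 3), extracellular
    j_i: np.ndarray   # (n_units, nx, ny, nz_m, 3), intracellular per unit
    j_b: np.ndarray   # (nx, ny, nz_b, 3), body/fat (empty if no fat)


def current_densities(
    phi: np.ndarray,
    state: mb.MembraneState,
    grid: SimulationGrid,
    cond: ConductivityModel,
) -> CurrentDensityField:
    """Ohm's-law currents from centred-difference potential gradients.

    φ_i^k = V_m^k + φ_e; gradients are taken per region box (one-sided at
    region boundaries).
    """
    nz_m = grid.n_muscle_z
    h = grid.spacing
    phi_e = phi[:, :, :nz_m]
    grad_e = np.stack(np.gradient(phi_e, *h), axis=-1)
    j_e = -cond.sigma_e_ax * grad_e

    n_units = state.v_m.shape[0]
    j_i = np.empty((n_units,) + phi_e.shape + (3,))
    for k in range(n_units):
        grad_i = np.stack(np.gradient(state.v_m[k] + phi_e, *h), axis=-1)
        j_i[k] = -cond.sigma_i_ax * grad_i

    if grid.shape[2] > nz_m:
        phi_b = phi[:, :, nz_m - 1 :]  # include interface layer for the stencil
        grad_b = np.stack(np.gradient(phi_b, *h), axis=-1)
        j_b = -cond.sigma_b * grad_b[:, :, 1:]
    else:
        j_b = np.zeros(phi_e.shape[:2] + (0, 3))
    return CurrentDensityField(j_e=j_e, j_i=j_i, j_b=j_b)


# ---------------------------------------------------------------------------
# coupled stepper
# ---------------------------------------------------------------------------


class MultiDomainModel:
    """Time stepper for the coupled electric problem.

    Godunov splitting per PDE step of ``dt_pde`` (default 0.1 ms, the
    10 kHz output rate): (i) ``dt_pde/dt_ode`` membrane reaction substeps,
    (ii) elliptic solve for φ, (iii) implicit fibre diffusion of V_m.
    ``step()`` returns the φ field recorded after (ii), consistent with the
    post-reaction membrane state.
    """

    def __init__(
        self,
        grid: SimulationGrid,
        cond: ConductivityModel,
        motor_units: MotorUnitMap,
        stimulus: mb.StimulusProtocol | None = None,
        dt_pde: float = 0.1,
        dt_ode: float = 0.01,
    ):
        if dt_ode > 0.02:
            raise ConfigurationError("dt_ode must be <= 0.02 ms")
        n_sub = dt_pde / dt_ode
        if abs(n_sub - round(n_sub)) > 1e-9:
            raise ConfigurationError("dt_pde must be a multiple of dt_ode")
        self.grid = grid
        self.cond = cond
        self.motor_units = motor_units
        self.stimulus = stimulus
        self.dt_pde = dt_pde
        self.dt_ode = dt_ode
        self.n_sub = int(round(n_sub))
        self.params = cond.params
        self.operator = assemble_elliptic_operator(grid, cond, motor_units)
        self._lu = self.operator.factorise()
        self.diffusion = FibreDiffusion.build(
            grid.shape[0], grid.spacing[0], self.params.sigma_i_l,
            self.params.c_m, self.params.a_m, dt_pde,
        )
        self.state = mb.MembraneState.resting(grid.muscle_shape, motor_units.n_units)
        self._stim_mask = motor_units.nmj_mask if stimulus is not None else None

    def step(self) -> np.ndarray:
        """Advance one PDE step; returns φ on the tissue box (mV)."""
        mb.integrate_reaction(
            self.state, self.dt_ode, self.n_sub, self.params.c_m,
            self.stimulus, self._stim_mask,
        )
        phi = solve_extracellular(
            self._lu, self.operator, self.state, self.motor_units,
            self.params.sigma_i_l,
        )
        diffuse_vm(self.state, phi[:, :, : self.grid.n_muscle_z], self.diffusion)
        return phi

    def currents(self, phi: np.ndarray) -> CurrentDensityField:
        return current_densities(phi, self.state, self.grid, self.cond)
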