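"""Magnetostatic vector-potential solver and per-domain field decomposition.

The magnetic vector potential obeys, componentwise, a Poisson equation
``div grad A = −µ0 j`` with the domain-wise conduction currents as sources
(muscle: extracellular plus recruitment-weighted intracellular currents;
fat: body currents; air: source free), A and its gradient continuous across
interfaces (uniform permeability), and A → 0 far away.  The far-field
condition is truncated to zero Dirichlet on a finite air box padding the
tissue; B = curl A.

Discretisation is the scalar 7-point Laplacian on the padded grid.  Two
equivalent solution paths are provided:

* :func:`assemble_poisson_operator` + a sparse factorisation (small grids,
  tests);
* :class:`VectorPotentialSolver`, a fast DST-I spectral solve of exactly
  the same discrete operator (production).

Because the operator is symmetric, the field at a sensor is also a linear
functional of the sources: :class:`SensorFieldEvaluator` precomputes
discrete Green's rows (one spectral solve per evaluation point) and obtains
per-time-step, per-domain sensor B values by dot products — identical, up
to roundoff, to solving the full field and taking the discrete curl.

Internal magnetic units are SI (metres, A/m², tesla); inputs arrive in the
package's cm / µA/cm² convention and B is reported in pT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft
import scipy.sparse as sp

from .geometry import ConfigurationError, SimulationGrid

CM_TO_M = 0.01
UA_PER_CM2_TO_A_PER_M2 = 0.01   # 1 µA/cm² = 0.01 A/m²
T_TO_PT = 1e12

DOMAINS = ("extracellular", "intracellular_active", "intracellular_passive", "body")


@dataclass(frozen=True)
class PaddedBox:
    """Air-padded computational box for the magnetostatic problem.

    The tissue grid sits at ``tissue_offset`` (node index of tissue node
    (0,0,0) in padded coordinates); the outermost node layer carries the
    zero-Dirichlet truncation of the far-field condition.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]   # cm
    origin: tuple[float, float, float]    # cm
    tissue_offset: tuple[int, int, int]
    tissue_shape: tuple[int, int, int]

    @property
    def interior_shape(self) -> tuple[int, int, int]:
        return tuple(n - 2 for n in self.shape)

    @classmethod
    def from_grid(cls, grid: SimulationGrid, padding: float | None = None) -> "PaddedBox":
        pad = grid.air_padding if padding is None else padding
        if pad <= 0:
            raise ConfigurationError("magnetic solve requires air padding > 0")
        npad = []
        for a in range(3):
            n = pad / grid.spacing[a]
            npad.append(int(round(n)))
            if npad[-1] < 1:
                raise ConfigurationError("air padding below one grid cell")
        shape = tuple(grid.shape[a] + 2 * npad[a] for a in range(3))
        origin = tuple(grid.origin[a] - npad[a] * grid.spacing[a] for a in range(3))
        return cls(
            shape=shape,
            spacing=grid.spacing,
            origin=origin,
            tissue_offset=tuple(npad),
            tissue_shape=grid.shape,
        )

    def embed(self, tissue_field: np.ndarray) -> np.ndarray:
        """Place a per-tissue-node array into the padded box (zeros outside)."""
        out = np.zeros(self.shape + tissue_field.shape[3:])
        ox, oy, oz = self.tissue_offset
        tx, ty, tz = tissue_field.shape[:3]
        out[ox : ox + tx, oy : oy + ty, oz : oz + tz] = tissue_field
        return out


def assemble_poisson_operator(box: PaddedBox) -> sp.csr_matrix:
    """Sparse 7-point Laplacian over interior nodes, Dirichlet eliminated.

    Returns ``div grad`` (symmetric, negative definite) scaled in 1/m².
    """
    shape = box.interior_shape
    h2 = [(s * CM_TO_M) ** 2 for s in box.spacing]
    n = int(np.prod(shape))
    idx = np.arange(n).reshape(shape)
    diag = np.zeros(n)
    rows, cols, vals = [], [], []
    for axis in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(0, -1)
        sl_hi[axis] = slice(1, None)
        i_lo = idx[tuple(sl_lo)].ravel()
        i_hi = idx[tuple(sl_hi)].ravel()
        w = 1.0 / h2[axis]
        rows.extend((i_lo, i_hi))
        cols.extend((i_hi, i_lo))
        vals.extend((np.full(i_lo.size, w), np.full(i_lo.size, w)))
        diag -= 2.0 * w  # Dirichlet: ghost values are zero, full -2/h² stays
    rows.append(idx.ravel())
    cols.append(idx.ravel())
    vals.append(diag)
    return sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()


class VectorPotentialSolver:
    """Spectral (DST-I) solver of the discrete Dirichlet Poisson problem.

    Diagonalises the same 7-point Laplacian as
    :func:`assemble_poisson_operator` in the sine basis; each solve costs
    two 3-D fast transforms.
    """

    def __init__(self, box: PaddedBox):
        self.box = box
        shape = box.interior_shape
        lam = np.zeros(shape)
        for a in range(3):
            m = shape[a]
            h = box.spacing[a] * CM_TO_M
            ev = (2.0 - 2.0 * np.cos(np.pi * np.arange(1, m + 1) / (m + 1))) / h**2
            lam += ev.reshape([-1 if i == a else 1 for i in range(3)])
        self._lam = lam

    def solve_interior(self, rhs: np.ndarray) -> np.ndarray:
        """Solve ``−div grad u = rhs`` on interior nodes (Dirichlet zero)."""
        u_hat = scipy.fft.dstn(rhs, type=1, norm="ortho") / self._lam
        return scipy.fft.idstn(u_hat, type=1, norm="ortho")

    def solve_component(self, mu0_j: np.ndarray) -> np.ndarray:
        """Solve ``div grad A = −mu0_j`` over the padded box (boundary = 0)."""
        if mu0_j.shape != self.box.shape:
            raise ConfigurationError("source field must live on the padded box")
        a = np.zeros(self.box.shape)
        a[1:-1, 1:-1, 1:-1] = self.solve_interior(mu0_j[1:-1, 1:-1, 1:-1])
        return a

    def green_row(self, point: tuple[int, int, int]) -> np.ndarray:
        """Discrete Green's function of ``−div grad`` for one padded-grid node.

        ``point`` is in padded-box node coordinates (must be interior).
        Returns the interior 3-D array g with ``(−div grad) g = δ_point``.
        """
        rhs = np.zeros(self.box.interior_shape)
        rhs[point[0] - 1, point[1] - 1, point[2] - 1] = 1.0
        return self.solve_interior(rhs)


def solve_vector_potential(
    box: PaddedBox,
    j_si: np.ndarray,
    mu_0: float = 4.0e-7 * np.pi,
    solver: VectorPotentialSolver | None = None,
) -> np.ndarray:
    """Full vector-potential field from a padded-box current density.

    ``j_si``: (nx, ny, nz, 3) in A/m² (zero in air).  Returns A in T·m on
    the padded box.  Contributions of current subsets superpose linearly.
    """
    solver = solver or VectorPotentialSolver(box)
    a = np.empty(box.shape + (3,))
    for c in range(3):
        a[..., c] = solver.solve_component(mu_0 * j_si[..., c])
    return a


def curl(a: np.ndarray, spacing_cm) -> np.ndarray:
    """Discrete curl, centred differences (one-sided at box boundaries).

    ``a`` is (nx, ny, nz, 3) in T·m with spacing in cm; returns B in T with
    component order (B_l∥, B_t∥, B_t⊥) following the grid axes.
    """
    h = [s * CM_TO_M for s in spacing_cm]
    dz_dy = np.gradient(a[..., 2], h[1], axis=1)
    dy_dz = np.gradient(a[..., 1], h[2], axis=2)
    dx_dz = np.gradient(a[..., 0], h[2], axis=2)
    dz_dx = np.gradient(a[..., 2], h[0], axis=0)
    dy_dx = np.gradient(a[..., 1], h[0], axis=0)
    dx_dy = np.gradient(a[..., 0], h[1], axis=1)
    return np.stack([dz_dy - dy_dz, dx_dz - dz_dx, dy_dx - dx_dy], axis=-1)


def divergence(field: np.ndarray, spacing_cm) -> np.ndarray:
    """Discrete divergence with the same np.gradient stencils as curl."""
    h = [s * CM_TO_M for s in spacing_cm]
    return sum(np.gradient(field[..., a], h[a], axis=a) for a in range(3))


class SensorFieldEvaluator:
    """Per-sensor magnetic field via precomputed discrete Green's rows.

    For each sensor the three B components are centred differences of A at
    the six axis neighbours; by symmetry of the Laplacian each required
    A-point value is a dot product of a Green's row with the source.  Rows
    are restricted to the tissue support (sources vanish in air) and shared
    between sensors.  ``evaluate`` then maps a set of per-domain SI current
    fields to B vectors in pT.
    """

    def __init__(
        self,
        box: PaddedBox,
        sensors_tissue_idx: list[tuple[int, int, int]],
        mu_0: float = 4.0e-7 * np.pi,
    ):
        self.box = box
        self.mu_0 = mu_0
        self.solver = VectorPotentialSolver(box)
        off = box.tissue_offset
        self.sensors = [tuple(p[a] + off[a] for a in range(3)) for p in sensors_tissue_idx]
        ish = box.interior_shape
        for s in self.sensors:
            for a in range(3):
                if not 1 <= s[a] < box.shape[a] - 1:
                    raise ConfigurationError("sensor too close to the padded boundary")
        # tissue-support flat indices within the interior array
        tix = [np.arange(box.tissue_shape[a]) + off[a] - 1 for a in range(3)]
        grids = np.meshgrid(*tix, indexing="ij")
        self._support = np.ravel_multi_index(
            [g.ravel() for g in grids], ish
        )
        self._rows: dict[tuple[int, int, int], np.ndarray] = {}
        # difference rows per sensor and axis: (g(s+e_a) − g(s−e_a)) / (2 h_a)
        self.diff_rows = []
        for s in self.sensors:
            per_axis = []
            for a in range(3):
                h = box.spacing[a] * CM_TO_M
                gp = self._row(tuple(s[i] + (i == a) for i in range(3)))
                gm = self._row(tuple(s[i] - (i == a) for i in range(3)))
                per_axis.append((gp - gm) / (2.0 * h))
            self.diff_rows.append(per_axis)

    def _row(self, point: tuple[int, int, int]) -> np.ndarray:
        if point not in self._rows:
            g = self.solver.green_row(point)
            self._rows[point] = g.ravel()[self._support].copy()
        return self._rows[point]

    @property
    def n_green_solves(self) -> int:
        return len(self._rows)

    def evaluate(self, j_si_tissue: np.ndarray) -> np.ndarray:
        """B (pT) at every sensor for one tissue-box current field (A/m²)."""
        j = j_si_tissue.reshape(-1, 3)
        out = np.empty((len(self.sensors), 3))
        for i, (dx, dy, dz) in enumerate(self.diff_rows):
            a_x = (dx @ j[:, 0], dy @ j[:, 0], dz @ j[:, 0])  # dA_x/daxis ...
            a_y = (dx @ j[:, 1], dy @ j[:, 1], dz @ j[:, 1])
            a_z = (dx @ j[:, 2], dy @ j[:, 2], dz @ j[:, 2])
            out[i, 0] = a_z[1] - a_y[2]
            out[i, 1] = a_x[2] - a_z[0]
            out[i, 2] = a_y[0] - a_x[1]
        return out * self.mu_0 * T_TO_PT
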