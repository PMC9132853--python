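"""Discretised tissue model: grid, regions, fibres, conductivities, motor units.

The simulated anatomy is a cuboid skeletal-muscle sample (L x W x H =
4.0 x 1.5 x 2.0 cm by default) with the fibres aligned to the longest edge,
optionally covered by a subcutaneous fat slab of thickness ``d_fat`` on the
face with the largest surface-normal coordinate, and embedded in an air box
for the magnetostatic problem.

Axis semantics (fixed throughout the package):

* axis 0 — ``x_l∥``  : fibre direction (longitudinal),
* axis 1 — ``x_t∥``  : transverse, tangential to the recording surface,
* axis 2 — ``x_t⊥``  : normal to the recording surface.

All lengths are centimetres, conductivities mS/cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# region labels
MUSCLE = 0
BODY = 1
AIR = 2


class ConfigurationError(ValueError):
    """Raised for inconsistent geometry / experiment configuration."""


@dataclass(frozen=True)
class TissueParameters:
    """Electrical material constants of the tissue model.

    Defaults are the reference parameter set for skeletal muscle: a
    rank-one intracellular conductivity along the fibre direction (the
    transverse intracellular conductivity is zero in the homogenised
    fibre-matrix picture), an axisymmetric extracellular tensor, isotropic
    fat, and Hodgkin–Huxley-type membrane constants.
    """

    sigma_i_l: float = 8.93   # longitudinal intracellular conductivity, mS/cm
    sigma_i_t: float = 0.0    # transverse intracellular conductivity, mS/cm
    sigma_e_l: float = 6.7    # longitudinal extracellular conductivity, mS/cm
    sigma_e_t: float = 3.35   # transverse extracellular conductivity, mS/cm
    sigma_b: float = 0.4      # fat/body conductivity (isotropic), mS/cm
    c_m: float = 1.0          # membrane capacitance, uF/cm^2
    a_m: float = 500.0        # fibre surface-to-volume ratio, 1/cm
    mu_0: float = 4.0e-7 * np.pi  # vacuum permeability, T*m/A

    def __post_init__(self) -> None:
        for name in ("sigma_i_l", "sigma_i_t", "sigma_e_l", "sigma_e_t", "sigma_b"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.c_m <= 0 or self.a_m <= 0:
            raise ConfigurationError("c_m and a_m must be positive")


@dataclass(frozen=True)
class SimulationGrid:
    """Structured regular grid with region labels.

    Nodes sit on the lattice ``origin + index * spacing``.  ``region`` holds
    one of :data:`MUSCLE`, :data:`BODY`, :data:`AIR` per node of the tissue
    box (muscle plus fat slab); the air padding used by the magnetic solver
    is represented implicitly through ``air_padding`` rather than stored
    node-by-node.
    """

    shape: tuple[int, int, int]          # nodes per axis of the tissue box
    spacing: tuple[float, float, float]  # cm
    origin: tuple[float, float, float]   # cm, coordinate of node (0,0,0)
    region: np.ndarray                   # (nx, ny, nz) int8 labels
    n_muscle_z: int                      # muscle layers along axis 2
    air_padding: float                   # cm of air on every side (magnetics)

    @property
    def muscle_mask(self) -> np.ndarray:
        return self.region == MUSCLE

    @property
    def body_mask(self) -> np.ndarray:
        return self.region == BODY

    @property
    def muscle_shape(self) -> tuple[int, int, int]:
        nx, ny, _ = self.shape
        return (nx, ny, self.n_muscle_z)

    @property
    def muscle_surface_index(self) -> int:
        """Index along axis 2 of the muscle face with largest x_t⊥."""
        return self.n_muscle_z - 1

    @property
    def surface_index(self) -> int:
        """Index along axis 2 of the recording surface (muscle or body)."""
        return self.shape[2] - 1

    def coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def node_coord(self, index: tuple[int, int, int]) -> tuple[float, float, float]:
        return tuple(self.origin[a] + self.spacing[a] * index[a] for a in range(3))

    def snap(self, axis: int, coordinate: float) -> int:
        """Nearest grid line along ``axis`` (round-half-even on the index)."""
        idx = int(np.round((coordinate - self.origin[axis]) / self.spacing[axis]))
        if not 0 <= idx < self.shape[axis]:
            raise ConfigurationError(
                f"coordinate {coordinate} cm outside the grid on axis {axis}"
            )
        return idx


@dataclass(frozen=True)
class FibreField:
    """Unit fibre-direction vector per muscle node, shape (nx, ny, nz_m, 3)."""

    f: np.ndarray

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.f, axis=-1)
        if not np.allclose(norms, 1.0, atol=1e-10):
            raise ConfigurationError("fibre vectors must be unit length")


@dataclass(frozen=True)
class MotorUnitMap:
    """Motor-unit territories on the muscle grid.

    ``f_r`` is the per-unit recruitment-density field (volume fraction of
    fibres of unit k among all fibres at a point); in the reference
    experiments it is an indicator of the territory, and the territories
    partition the muscle nodes.
    """

    n_units: int
    f_r: np.ndarray          # (n_units, nx, ny, nz_m) in [0, 1]
    nmj_mask: np.ndarray     # (n_units, nx, ny, nz_m) bool, stimulus nodes
    mu1_line: tuple[int, int]  # (iy, iz) of the recruited-fibre line

    def territory(self, k: int) -> np.ndarray:
        return self.f_r[k] > 0


@dataclass(frozen=True)
class ConductivityModel:
    """Per-axis conductivities of the grid (diagonal tensors).

    The fibre direction is required to be grid aligned, which makes every
    conductivity tensor diagonal and the finite-difference stencil a plain
    7-point one.  ``sigma_e_ax``/``sigma_i_ax`` give the diagonal entries
    per muscle node and axis; body nodes carry the isotropic ``sigma_b``.
    """

    sigma_e_ax: np.ndarray   # (nx, ny, nz_m, 3)
    sigma_i_ax: np.ndarray   # (nx, ny, nz_m, 3) — identical for every unit
    sigma_b: float
    params: TissueParameters = field(repr=False, default_factory=TissueParameters)

    def combined_muscle(self) -> np.ndarray:
        """Diagonal of σ_e + σ_i, the tensor of the φ_e operator in muscle."""
        return self.sigma_e_ax + self.sigma_i_ax


def build_grid(
    L: float = 4.0,
    W: float = 1.5,
    H: float = 2.0,
    d_fat: float = 0.0,
    spacing=0.1,
    air_padding: float = 4.0,
) -> SimulationGrid:
    """Build the labelled tissue grid.

    Muscle occupies ``[0,L] x [0,W] x [0,H]``; the fat slab, if any, covers
    ``z in [H, H+d_fat]``.  ``spacing`` is a scalar or a per-axis triple;
    dimensions must be integer multiples of the spacing (within rounding
    tolerance).
    """
    if np.isscalar(spacing):
        spacing = (float(spacing),) * 3
    spacing = tuple(float(s) for s in spacing)
    if min(spacing) <= 0:
        raise ConfigurationError("spacing must be positive")
    if min(L, W, H) <= 0:
        raise ConfigurationError("muscle dimensions must be positive")
    if d_fat < 0:
        raise ConfigurationError("fat thickness must be non-negative")
    if air_padding <= 0:
        raise ConfigurationError("air padding must be positive")

    def n_cells(length: float, h: float, name: str) -> int:
        n = length / h
        if abs(n - round(n)) > 1e-6:
            raise ConfigurationError(
                f"{name}={length} cm is not a multiple of spacing={h} cm"
            )
        return int(round(n))

    nx = n_cells(L, spacing[0], "L") + 1
    ny = n_cells(W, spacing[1], "W") + 1
    nz_m = n_cells(H, spacing[2], "H") + 1
    nz_b = n_cells(d_fat, spacing[2], "d_fat") if d_fat > 0 else 0

    region = np.full((nx, ny, nz_m + nz_b), MUSCLE, dtype=np.int8)
    region[:, :, nz_m:] = BODY
    return SimulationGrid(
        shape=(nx, ny, nz_m + nz_b),
        spacing=spacing,
        origin=(0.0, 0.0, 0.0),
        region=region,
        n_muscle_z=nz_m,
        air_padding=float(air_padding),
    )


def uniform_fibres(grid: SimulationGrid, direction=(1.0, 0.0, 0.0)) -> FibreField:
    """Constant fibre field; the reference experiments use f = (1, 0, 0)."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    f = np.broadcast_to(d, grid.muscle_shape + (3,)).copy()
    return FibreField(f=f)


def build_motor_unit_map(
    grid: SimulationGrid,
    depth_d: float,
    mu1_xt_par: float = 0.75,
    nmj_xl: float = 1.0,
) -> MotorUnitMap:
    """Two-unit recruitment map for the selective-stimulation experiments.

    The recruited unit (MU1) is the single fibre-parallel line of nodes at
    the cross-section ``(x_t∥, x_t⊥) = (mu1_xt_par, H − depth_d)``; the
    passive unit (MU2) is every other muscle node.  The neuromuscular
    junction of MU1 is the node of that line at ``x_l∥ = nmj_xl``.
    Coordinates snap to the nearest grid line.
    """
    H = (grid.n_muscle_z - 1) * grid.spacing[2] + grid.origin[2]
    if not 0 < depth_d < H:
        raise ConfigurationError(f"activation depth d={depth_d} outside muscle (0, {H})")
    iy = grid.snap(1, mu1_xt_par)
    iz = grid.snap(2, H - depth_d)
    if iz >= grid.n_muscle_z:
        raise ConfigurationError("MU1 line lies outside the muscle region")
    ix_nmj = grid.snap(0, nmj_xl)

    shape = grid.muscle_shape
    f_r = np.zeros((2,) + shape)
    f_r[0, :, iy, iz] = 1.0
    f_r[1] = 1.0 - f_r[0]
    nmj = np.zeros((2,) + shape, dtype=bool)
    nmj[0, ix_nmj, iy, iz] = True
    return MotorUnitMap(n_units=2, f_r=f_r, nmj_mask=nmj, mu1_line=(iy, iz))


def build_conductivities(
    grid: SimulationGrid,
    fibres: FibreField,
    params: TissueParameters | None = None,
) -> ConductivityModel:
    """Per-node diagonal conductivities from the fibre field.

    σ_i = σ_i_l f⊗f (+ σ_i_t on the orthogonal complement, zero by default)
    and σ_e = σ_e_l f⊗f + σ_e_t (I − f⊗f).  The fibre direction must be
    aligned with a grid axis so the tensors stay diagonal.
    """
    params = params or TissueParameters()
    f = fibres.f
    aligned = np.isclose(np.abs(f), 1.0) | np.isclose(f, 0.0)
    if not aligned.all():
        raise ConfigurationError("fibre field must be grid-axis aligned")
    ff = f * f  # diagonal of f⊗f
    sigma_i = params.sigma_i_l * ff + params.sigma_i_t * (1.0 - ff)
    sigma_e = params.sigma_e_l * ff + params.sigma_e_t * (1.0 - ff)
    return ConductivityModel(
        sigma_e_ax=sigma_e, sigma_i_ax=sigma_i, sigma_b=params.sigma_b, params=params
    )


def conductivity_tensor(sigma_l: float, sigma_t: float, f) -> np.ndarray:
    """Full 3x3 axisymmetric tensor σ_l f⊗f + σ_t (I − f⊗f) for one fibre vector."""
    f = np.asarray(f, dtype=float)
    outer = np.outer(f, f)
    return sigma_l * outer + sigma_t * (np.eye(3) - outer)
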