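"""Array-container export of grids, field snapshots and channel series.

NPZ keeps the dependency surface minimal while remaining loadable from any
scientific Python stack; channel series go to CSV via the CLI/pandas.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import SimulationGrid
from .membrane import MembraneState


def save_grid(grid: SimulationGrid, path) -> None:
    """Write node coordinates, spacings and region labels to an .npz file."""
    np.savez_compressed(
        Path(path),
        region=grid.region,
        spacing=np.asarray(grid.spacing),
        origin=np.asarray(grid.origin),
        x=grid.coords(0),
        y=grid.coords(1),
        z=grid.coords(2),
        n_muscle_z=grid.n_muscle_z,
        air_padding=grid.air_padding,
    )


def save_field_snapshot(
    path,
    grid: SimulationGrid,
    phi: np.ndarray,
    state: MembraneState | None = None,
    time_ms: float | None = None,
) -> None:
    """Write one time step of φ (tissue box, mV) and optionally V_m^k/gates."""
    data = {
        "phi": phi,
        "spacing": np.asarray(grid.spacing),
        "origin": np.asarray(grid.origin),
        "n_muscle_z": grid.n_muscle_z,
    }
    if time_ms is not None:
        data["time_ms"] = time_ms
    if state is not None:
        data["v_m"] = state.v_m
        for name, arr in state.gates.items():
            data[f"gate_{name}"] = arr
    np.savez_compressed(Path(path), **data)
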