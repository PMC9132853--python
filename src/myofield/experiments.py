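"""In-silico experiment protocol: runs, sweeps and report tables.

The reference protocol stimulates a single recruited fibre line at depths
d = 0.3 … 1.1 cm below the recording surface of a 4 × 1.5 × 2 cm muscle,
with fat layers of 0, 0.2 and 0.4 cm, and observes the measurement vector
[φ, B_l∥, B_t∥, B_t⊥] from a single surface channel at
(x_l∥, x_t∥) = (2.5, 0.6) cm and from a channel line across the fibres at
x_l∥ = 2.5 cm.  The fat sweep keeps the source–sensor distance constant
(d = 0.9, 0.7, 0.5 cm for d_fat = 0, 0.2, 0.4 cm).  Reported tables are
RMS/MNF normalised to the shallowest depth, fat-layer RMS factors against
the no-fat reference, and per-domain contributions to the magnetic field
normalised by the total observable field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from . import electric, magnetic, membrane, recording
from .geometry import (
    ConfigurationError,
    TissueParameters,
    build_conductivities,
    build_grid,
    build_motor_unit_map,
    uniform_fibres,
)

DEPTHS = (0.3, 0.5, 0.7, 0.9, 1.1)
FAT_THICKNESSES = (0.0, 0.2, 0.4)
# fat sweep at constant source–sensor distance of 0.9 cm
FAT_SWEEP_PAIRS = {0.0: 0.9, 0.2: 0.7, 0.4: 0.5}

_METRIC_ROWS = (
    ("EMG", "phi"),
    ("MMG (x_l_par)", "B_l_par"),
    ("MMG (x_t_par)", "B_t_par"),
    ("MMG (x_t_perp)", "B_t_perp"),
)


@dataclass(frozen=True)
class ExperimentConfig:
    """Fully specifies one deterministic simulation run."""

    depth: float = 0.3            # activation depth below the muscle surface, cm
    d_fat: float = 0.0            # fat-layer thickness, cm
    L: float = 4.0                # muscle length (fibre direction), cm
    W: float = 1.5                # muscle width, cm
    H: float = 2.0                # muscle height, cm
    # grid spacing, cm: per-axis (x_l∥, x_t∥, x_t⊥); the default transverse
    # pitch 0.075 cm puts the recruited-fibre cross-section (0.75 cm) and the
    # reference channel (0.6 cm) exactly on grid lines
    spacing: tuple = (0.1, 0.075, 0.1)
    air_padding: float = 4.0      # air box for the magnetic solve, cm
    duration: float = 30.0        # simulated time, ms
    dt_pde: float = 0.1           # splitting/output step, ms
    dt_ode: float = 0.01          # membrane reaction substep, ms
    stim_onset: float = 1.0       # ms
    stim_amplitude: float = 700.0  # homogenised pulse amplitude (see membrane)
    stim_duration: float = 0.1    # ms
    stimulate: bool = True
    channel: tuple[float, float] = (2.5, 0.6)   # (x_l∥, x_t∥) of the channel, cm
    line_xl: float = 2.5          # x_l∥ of the cross-fibre channel line, cm
    line_pitch: float | None = None  # channel pitch, defaults to grid spacing
    magnetic: bool = True         # evaluate B at the single channel
    magnetic_line: bool = False   # evaluate B along the channel line
    contributions: bool = False   # per-domain decomposition at the channel
    mu1_xt_par: float = 0.75      # MU1 cross-section coordinate, cm
    nmj_xl: float = 1.0           # NMJ coordinate along the fibre, cm

    def line_positions(self) -> np.ndarray:
        pitch = self.line_pitch or (
            self.spacing[1] if not np.isscalar(self.spacing) else self.spacing
        )
        n = int(round(self.W / pitch)) + 1
        return np.arange(n) * pitch


@dataclass
class ExperimentResult:
    """Channel series and metadata of one run (deterministic given config)."""

    config: ExperimentConfig
    times: np.ndarray                          # ms, 10 kHz
    channel: recording.ChannelRecording        # single-channel measurement vector
    line_positions: np.ndarray                 # x_t∥ of line channels, cm
    emg_line: np.ndarray                       # (nt, n_channels) φ, mV
    b_line: np.ndarray | None = None           # (nt, n_channels, 3) B, pT
    contributions: dict[str, np.ndarray] = field(default_factory=dict)
    # per-domain (nt, 3) B series at the single channel, plus "total"

    def component_rms(self, name: str) -> float:
        return recording.rms(self.channel.component(name))

    def component_mnf(self, name: str) -> float:
        freqs, power = recording.psd(self.channel.component(name))
        return recording.mean_frequency(freqs, power)

    def emg_line_rms(self) -> np.ndarray:
        return np.sqrt(np.mean(self.emg_line**2, axis=0))

    def b_line_rms(self) -> np.ndarray:
        if self.b_line is None:
            raise ValueError("run did not evaluate the magnetic channel line")
        return np.sqrt(np.mean(self.b_line**2, axis=0))

    def metrics_table(self) -> pd.DataFrame:
        rows = {}
        for label, comp in _METRIC_ROWS:
            rows[label] = {
                "RMS": self.component_rms(comp),
                "MNF": self.component_mnf(comp),
            }
        return pd.DataFrame(rows).T


def _sensor_nodes(cfg: ExperimentConfig, grid):
    """Tissue-node indices of the single channel and the channel line."""
    iz = grid.surface_index
    ch = (grid.snap(0, cfg.channel[0]), grid.snap(1, cfg.channel[1]), iz)
    line = [
        (grid.snap(0, cfg.line_xl), grid.snap(1, y), iz)
        for y in cfg.line_positions()
    ]
    return ch, line


def run_experiment(
    cfg: ExperimentConfig,
    evaluator_cache: dict | None = None,
) -> ExperimentResult:
    """Execute geometry → membrane → electric → magnetic → recording.

    ``evaluator_cache`` (optional dict) re-uses the magnetic Green's rows
    between runs that share a geometry and sensor layout.
    """
    out_every = cfg.dt_pde and round(0.1 / cfg.dt_pde)
    if abs(out_every * cfg.dt_pde - 0.1) > 1e-9:
        raise ConfigurationError("dt_pde must divide the 0.1 ms output interval")
    out_every = int(out_every)

    params = TissueParameters()
    grid = build_grid(cfg.L, cfg.W, cfg.H, cfg.d_fat, cfg.spacing, cfg.air_padding)
    fibres = uniform_fibres(grid)
    cond = build_conductivities(grid, fibres, params)
    mus = build_motor_unit_map(grid, cfg.depth, cfg.mu1_xt_par, cfg.nmj_xl)
    stim = (
        membrane.StimulusProtocol(
            amplitude=cfg.stim_amplitude,
            duration=cfg.stim_duration,
            onset=cfg.stim_onset,
            a_m=params.a_m,
        )
        if cfg.stimulate
        else None
    )
    model = electric.MultiDomainModel(
        grid, cond, mus, stimulus=stim, dt_pde=cfg.dt_pde, dt_ode=cfg.dt_ode
    )

    ch_node, line_nodes = _sensor_nodes(cfg, grid)
    need_b = cfg.magnetic or cfg.magnetic_line or cfg.contributions
    evaluator = None
    if need_b:
        sensors = [ch_node] + (line_nodes if cfg.magnetic_line else [])
        key = (grid.shape, grid.spacing, grid.air_padding, tuple(sensors))
        if evaluator_cache is not None and key in evaluator_cache:
            evaluator = evaluator_cache[key]
        else:
            box = magnetic.PaddedBox.from_grid(grid)
            evaluator = magnetic.SensorFieldEvaluator(box, sensors, params.mu_0)
            if evaluator_cache is not None:
                evaluator_cache[key] = evaluator

    n_steps = int(round(cfg.duration / cfg.dt_pde))
    n_out = n_steps // out_every
    times = 0.1 * np.arange(1, n_out + 1)
    nz_m = grid.n_muscle_z

    emg_ch = np.zeros(n_out)
    emg_line = np.zeros((n_out, len(line_nodes)))
    b_series = {name: np.zeros((n_out, len(evaluator.sensors), 3))
                for name in magnetic.DOMAINS} if cfg.contributions else {}
    b_total = np.zeros((n_out, len(evaluator.sensors), 3)) if need_b else None

    i_out = 0
    for i_step in range(n_steps):
        phi = model.step()
        if (i_step + 1) % out_every:
            continue
        emg_ch[i_out] = phi[ch_node]
        for j, node in enumerate(line_nodes):
            emg_line[i_out, j] = phi[node]
        if need_b:
            cur = model.currents(phi)
            sources = domain_current_sources(cur, mus, grid)
            if cfg.contributions:
                total = np.zeros((len(evaluator.sensors), 3))
                for name in magnetic.DOMAINS:
                    b = evaluator.evaluate(sources[name])
                    b_series[name][i_out] = b
                    total += b
                b_total[i_out] = total
            else:
                b_total[i_out] = evaluator.evaluate(sum(sources.values()))
        i_out += 1

    ch_b = b_total[:, 0, :] if need_b else np.zeros((n_out, 3))
    series = np.column_stack([emg_ch, ch_b])
    channel = recording.ChannelRecording(
        position=grid.node_coord(ch_node), times=times, series=series
    )
    contributions = {}
    if cfg.contributions:
        contributions = {name: b_series[name][:, 0, :] for name in magnetic.DOMAINS}
        contributions["total"] = ch_b
    return ExperimentResult(
        config=cfg,
        times=times,
        channel=channel,
        line_positions=cfg.line_positions(),
        emg_line=emg_line,
        b_line=b_total[:, 1:, :] if cfg.magnetic_line else None,
        contributions=contributions,
    )


def domain_current_sources(
    currents: electric.CurrentDensityField, motor_units, grid
) -> dict[str, np.ndarray]:
    """Per-domain SI current fields (A/m²) on the tissue box.

    Intracellular currents are weighted by the recruitment density f_r;
    the four domains superpose to the total magnetic source.
    """
    nz_m = grid.n_muscle_z
    scale = magnetic.UA_PER_CM2_TO_A_PER_M2
    out = {}
    for name, j_muscle in (
        ("extracellular", currents.j_e),
        ("intracellular_active", motor_units.f_r[0][..., None] * currents.j_i[0]),
        ("intracellular_passive", motor_units.f_r[1][..., None] * currents.j_i[1]),
    ):
        a = np.zeros(grid.shape + (3,))
        a[:, :, :nz_m] = j_muscle * scale
        out[name] = a
    body = np.zeros(grid.shape + (3,))
    if grid.shape[2] > nz_m:
        body[:, :, nz_m:] = currents.j_b * scale
    out["body"] = body
    return out


# ---------------------------------------------------------------------------
# protocol sweeps and report tables
# ---------------------------------------------------------------------------


def run_depth_sweep(
    depths=DEPTHS,
    d_fat: float = 0.0,
    base: ExperimentConfig | None = None,
    evaluator_cache: dict | None = None,
) -> dict[float, ExperimentResult]:
    """Selective stimulation at several depths, fixed fat thickness."""
    base = base or ExperimentConfig()
    cache = {} if evaluator_cache is None else evaluator_cache
    return {
        d: run_experiment(replace(base, depth=d, d_fat=d_fat), cache) for d in depths
    }


def run_fat_sweep(
    pairs: dict[float, float] | None = None,
    base: ExperimentConfig | None = None,
    evaluator_cache: dict | None = None,
) -> dict[float, ExperimentResult]:
    """Fat-thickness sweep at constant source–sensor distance."""
    base = base or ExperimentConfig()
    pairs = pairs or FAT_SWEEP_PAIRS
    cache = {} if evaluator_cache is None else evaluator_cache
    return {
        d_fat: run_experiment(replace(base, depth=d, d_fat=d_fat), cache)
        for d_fat, d in pairs.items()
    }


def normalised_metrics(
    runs: dict[float, ExperimentResult], reference_depth: float | None = None
) -> pd.DataFrame:
    """Depth-sweep RMS/MNF table normalised to the shallowest depth."""
    depths = sorted(runs)
    ref = reference_depth if reference_depth is not None else depths[0]
    rows = {}
    for label, comp in _METRIC_ROWS:
        ref_rms = runs[ref].component_rms(comp)
        ref_mnf = runs[ref].component_mnf(comp)
        rows[f"{label}-RMS"] = [runs[d].component_rms(comp) / ref_rms for d in depths]
        rows[f"{label}-MNF"] = [runs[d].component_mnf(comp) / ref_mnf for d in depths]
    return pd.DataFrame(rows, index=pd.Index(depths, name="depth_cm")).T


def fat_sweep_factors(runs: dict[float, ExperimentResult]) -> pd.DataFrame:
    """RMS change factors of each component relative to the no-fat run."""
    if 0.0 not in runs:
        raise ValueError("fat sweep requires the no-fat reference run")
    fats = sorted(runs)
    rows = {}
    for label, comp in _METRIC_ROWS:
        ref = runs[0.0].component_rms(comp)
        rows[f"{label}-RMS factor"] = [runs[f].component_rms(comp) / ref for f in fats]
    return pd.DataFrame(rows, index=pd.Index(fats, name="d_fat_cm")).T


def contribution_report(result: ExperimentResult) -> pd.DataFrame:
    """Per-domain RMS of each B component normalised by the total field.

    Also re-verifies superposition closure: the per-sample sum of domain
    fields must equal the total field to solver tolerance.
    """
    if not result.contributions:
        raise ValueError("run was not executed with contributions=True")
    total = result.contributions["total"]
    stack = sum(result.contributions[n] for n in magnetic.DOMAINS)
    closure = np.max(np.abs(stack - total)) / max(np.max(np.abs(total)), 1e-300)
    if closure > 1e-10:
        raise ArithmeticError(f"superposition closure violated: {closure:.2e}")
    comps = ("B_l_par", "B_t_par", "B_t_perp")
    rows = {}
    for name in magnetic.DOMAINS + ("total",):
        series = result.contributions[name]
        rows[name] = [
            recording.rms(series[:, c]) / recording.rms(total[:, c])
            for c in range(3)
        ]
    return pd.DataFrame(rows, index=pd.Index(comps, name="component")).T


def config_to_dict(cfg: ExperimentConfig) -> dict:
    """Serialisable form of a configuration (reproducibility sidecar)."""
    return asdict(cfg)
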