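"""Hodgkin–Huxley membrane kinetics and the stimulus protocol.

The sarcolemma of each motor unit is represented by the classic
squid-axon membrane model in the physiological-voltage convention used by
the Physiome/CellML encoding: resting potential −75 mV, E_Na = +40 mV,
E_K = −87 mV, E_L = −64.387 mV, conductances g_Na = 120, g_K = 36,
g_L = 0.3 mS/cm².  Units: mV, ms, µA/cm², µF/cm².

The reaction step advances the gating variables with the Rush–Larsen
exponential update (exact for frozen rates, unconditionally stable) and the
transmembrane potential with forward Euler on the ionic current.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# conductances (mS/cm^2) and reversal potentials (mV)
G_NA = 120.0
G_K = 36.0
G_L = 0.3
E_REST = -75.0
E_NA = E_REST + 115.0
E_K = E_REST - 12.0
E_L = E_REST + 10.613

GATES = ("m", "h", "n")


class IntegrationError(RuntimeError):
    """Raised when the membrane state diverges (NaN / out of range)."""


def _vtrap(x: np.ndarray, y: float) -> np.ndarray:
    """x / (exp(x/y) - 1) with the analytic limit y at the removable pole."""
    x = np.asarray(x, dtype=float)
    out = np.full_like(x, float(y))
    nz = np.abs(x) > 1e-9
    xe = np.where(nz, x, 1.0)  # dummy to avoid 0/0 warnings
    out = np.where(nz, xe / np.expm1(xe / y), out)
    return out


def rates(v_m):
    """Voltage-dependent opening/closing rates (1/ms) of the m, h, n gates.

    Returns ``{"m": (alpha, beta), "h": ..., "n": ...}``.  Removable
    singularities of the alpha_m / alpha_n expressions are evaluated by
    their analytic limits.
    """
    v = np.asarray(v_m, dtype=float)
    alpha_m = 0.1 * _vtrap(-(v + 50.0), 10.0)
    beta_m = 4.0 * np.exp(-(v + 75.0) / 18.0)
    alpha_h = 0.07 * np.exp(-(v + 75.0) / 20.0)
    beta_h = 1.0 / (np.exp(-(v + 45.0) / 10.0) + 1.0)
    alpha_n = 0.01 * _vtrap(-(v + 65.0), 10.0)
    beta_n = 0.125 * np.exp(-(v + 75.0) / 80.0)
    return {"m": (alpha_m, beta_m), "h": (alpha_h, beta_h), "n": (alpha_n, beta_n)}


def steady_state_gates(v_m):
    """Gate steady states y∞ = α/(α+β) at a given potential."""
    r = rates(v_m)
    return {g: a / (a + b) for g, (a, b) in r.items()}


def ionic_current(v_m, m, h, n, i_stim=0.0):
    """Total ohmic membrane current density I_ion (µA/cm²).

    ``I_ion = g_Na m³h (V−E_Na) + g_K n⁴ (V−E_K) + g_L (V−E_L) − I_stim``;
    a positive ``i_stim`` (µA/cm², membrane area) depolarises.
    """
    v_m = np.asarray(v_m, dtype=float)
    i_na = G_NA * m**3 * h * (v_m - E_NA)
    i_k = G_K * n**4 * (v_m - E_K)
    i_l = G_L * (v_m - E_L)
    return i_na + i_k + i_l - i_stim


@dataclass(frozen=True)
class StimulusProtocol:
    """Single rectangular current pulse delivered at the NMJ nodes of MU1.

    ``amplitude`` is the homogenised tissue current density as configured
    for the in-silico experiments; the membrane-level current density is
    ``amplitude / a_m * 1000`` µA/cm² (mA→µA) with ``a_m`` the fibre
    surface-to-volume ratio, i.e. 1400 µA/cm² for the defaults — a robustly
    suprathreshold pulse depolarising the junction by ≈140 mV.
    """

    amplitude: float = 700.0   # mA/cm^2 (homogenised), see class docstring
    duration: float = 0.1      # ms
    onset: float = 1.0         # ms
    a_m: float = 500.0         # 1/cm

    @property
    def membrane_amplitude(self) -> float:
        """Membrane-area current density of the pulse, µA/cm²."""
        return self.amplitude / self.a_m * 1000.0

    def membrane_current(self, t: float) -> float:
        """Stimulus at time t (µA/cm², membrane area); 0 outside the pulse."""
        if self.onset <= t < self.onset + self.duration:
            return self.membrane_amplitude
        return 0.0


@dataclass
class MembraneState:
    """Transmembrane potential and gates per motor unit on the muscle grid.

    ``v_m`` has shape (n_units, nx, ny, nz); each gate the same.
    """

    v_m: np.ndarray
    gates: dict = field(default_factory=dict)  # {"m": arr, "h": arr, "n": arr}
    time: float = 0.0

    @classmethod
    def resting(cls, shape, n_units: int = 2) -> "MembraneState":
        v = np.full((n_units,) + tuple(shape), E_REST)
        y = steady_state_gates(E_REST)
        gates = {g: np.full_like(v, y[g]) for g in GATES}
        return cls(v_m=v, gates=gates, time=0.0)

    def copy(self) -> "MembraneState":
        return MembraneState(
            v_m=self.v_m.copy(),
            gates={g: a.copy() for g, a in self.gates.items()},
            time=self.time,
        )


def integrate_reaction(
    state: MembraneState,
    dt: float,
    n_steps: int = 1,
    c_m: float = 1.0,
    stimulus: StimulusProtocol | None = None,
    stim_mask: np.ndarray | None = None,
) -> MembraneState:
    """Advance the pointwise membrane ODEs (reaction part only) in place.

    Rush–Larsen update for the gates, forward Euler for V_m; ``dt`` must be
    ≤ 0.02 ms for a stable explicit potential update.  ``stim_mask`` is a
    boolean array (same shape as ``state.v_m``) selecting NMJ nodes.
    """
    if dt <= 0 or dt > 0.02:
        raise ValueError("reaction step requires 0 < dt <= 0.02 ms")
    v = state.v_m
    for _ in range(n_steps):
        i_stim = stimulus.membrane_current(state.time) if stimulus is not None else 0.0
        r = rates(v)
        for g in GATES:
            a, b = r[g]
            y_inf = a / (a + b)
            state.gates[g] = y_inf + (state.gates[g] - y_inf) * np.exp(-dt * (a + b))
        i_ion = ionic_current(v, state.gates["m"], state.gates["h"], state.gates["n"])
        if i_stim and stim_mask is not None:
            i_ion = i_ion - i_stim * stim_mask
        v += dt * (-i_ion) / c_m
        state.time += dt
    if not np.isfinite(v).all():
        bad = np.argwhere(~np.isfinite(v))[0]
        raise IntegrationError(
            f"membrane state diverged at node {tuple(bad)}, t={state.time:.3f} ms"
        )
    return state
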