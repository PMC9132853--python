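"""Virtual sensors and signal metrics for EMG/MMG recordings.

A channel is an idealised point sensor on the recording surface returning
the measurement vector ``[φ, B_l∥, B_t∥, B_t⊥]`` at 10 kHz, where φ is the
extracellular potential for muscle-surface sensors and the body potential
on top of a fat layer.  Metrics follow standard surface-EMG practice: RMS
over the analysis window, periodogram PSD, power-weighted mean frequency,
and the across-channel coefficient of variation of RMS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

SAMPLING_RATE = 10_000.0  # Hz

COMPONENTS = ("phi", "B_l_par", "B_t_par", "B_t_perp")


@dataclass(frozen=True)
class ChannelRecording:
    """Measurement-vector time series of one channel.

    ``series`` is (n_samples, 4): φ in mV, B components in pT, sampled at
    exactly 10 kHz.
    """

    position: tuple[float, float, float]   # cm
    times: np.ndarray                      # ms
    series: np.ndarray                     # (nt, 4)
    sampling_rate: float = SAMPLING_RATE

    def component(self, name: str) -> np.ndarray:
        return self.series[:, COMPONENTS.index(name)]


def sample_channel(times, phi_fields, grid, position):
    """Nearest-node φ series of a surface channel from a stored field history.

    ``phi_fields`` is (nt, nx, ny, nz) over the tissue box; ``position`` is
    ``(x_l∥, x_t∥)`` on the recording surface (the tissue face with the
    largest x_t⊥ — muscle surface without fat, body surface otherwise).
    Returns ``(node_index, series)``; the sensor is idealised and does not
    affect the fields.
    """
    xl, xt = position
    ix = grid.snap(0, xl)
    iy = grid.snap(1, xt)
    iz = grid.surface_index
    series = np.asarray(phi_fields)[:, ix, iy, iz]
    if len(series) != len(times):
        raise ValueError("time vector and field history disagree")
    return (ix, iy, iz), series


def rms(series: np.ndarray) -> float:
    """Root-mean-square of a series over the full analysis window."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    return float(np.sqrt(np.mean(x**2)))


def psd(series: np.ndarray, fs: float = SAMPLING_RATE, nfft: int | None = None):
    """Single-window periodogram of the zero-padded full window.

    Returns (frequencies in Hz, power spectral density).  Transient
    signals are analysed in one window; zero padding (default: next power
    of two at least four times the window) refines the frequency grid.
    """
    x = np.asarray(series, dtype=float)
    if nfft is None:
        nfft = int(2 ** np.ceil(np.log2(max(4 * x.size, 16))))
    freqs, power = scipy.signal.periodogram(
        x, fs=fs, nfft=nfft, window="boxcar", detrend=False, scaling="density"
    )
    return freqs, power


def mean_frequency(freqs: np.ndarray, power: np.ndarray) -> float:
    """Power-weighted mean frequency Σ f·P / Σ P (Hz); 0 for zero power."""
    total = np.sum(power)
    if total == 0:
        return 0.0
    return float(np.sum(freqs * power) / total)


def cov_across_channels(rms_values) -> float:
    """Coefficient of variation 100·std/mean (%) across channels."""
    x = np.asarray(rms_values, dtype=float)
    mean = x.mean()
    if mean == 0:
        raise ValueError("zero mean RMS across channels")
    return float(100.0 * x.std() / mean)


def zero_to_max_distance(positions: np.ndarray, rms_profile: np.ndarray) -> float:
    """Distance between the minimum-|RMS| channel and the maximum channel.

    For field components whose amplitude vanishes directly over the source
    (fibre-aligned and surface-normal MMG), the minimum-RMS channel marks
    the source position and the argmax channel the profile peak; their
    separation, resolved to channel pitch, grows with source depth.
    """
    positions = np.asarray(positions, dtype=float)
    prof = np.abs(np.asarray(rms_profile, dtype=float))
    if positions.shape != prof.shape or positions.size < 2:
        raise ValueError("positions and profile must match and hold >= 2 channels")
    return float(abs(positions[np.argmax(prof)] - positions[np.argmin(prof)]))
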