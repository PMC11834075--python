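"""Wavelet spectrograms, event-window PSDs and aperiodic (1/f) slope fits.

One Morlet definition serves the whole package: a fixed-cycle complex
Morlet (n_cycles = 6, so omega0 ~ 6 and sigma_t = n_cycles / (2 pi f)).
Spectrogram power is amplitude-normalised — a unit-amplitude tone yields
unit peak power at every analysis frequency.  The aperiodic slope
estimator converts that power to a spectral density by dividing by each
wavelet's equivalent noise bandwidth (which grows linearly with frequency
for fixed cycles) before the log10-log10 regression; without that
correction broadband 1/f^beta noise would appear one power of f shallower
than it is.  The flattening of this slope is commonly read as a shift of
the excitation/inhibition balance toward excitation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

DEFAULT_FREQS = np.arange(1.0, 201.0, 1.0)
N_CYCLES = 6.0
_POWER_FLOOR_REL = 1e-12


@dataclass
class WaveletSpectrogram:
    power: np.ndarray          # frequencies x time, amplitude-normalised
    freqs: np.ndarray
    times: np.ndarray
    fs_hz: float
    n_cycles: float = N_CYCLES

    def enbw_hz(self) -> np.ndarray:
        """Equivalent noise bandwidth of each wavelet, Hz (scales with f)."""
        sigma_t = self.n_cycles / (2.0 * np.pi * self.freqs)
        return 1.0 / (np.sqrt(np.pi) * sigma_t)


@dataclass
class SpectralFit:
    slope: float
    offset: float
    r2: float
    window: tuple = (0.0, 0.0)
    n_floored: int = 0


def morlet_spectrogram(trace: np.ndarray, fs_hz: float,
                       freqs: np.ndarray = DEFAULT_FREQS,
                       n_cycles: float = N_CYCLES) -> WaveletSpectrogram:
    """Complex Morlet transform, power = |coefficient|^2.

    Wavelets are L1-normalised on their envelope so that a tone of
    amplitude A gives peak power A^2 regardless of frequency.  Traces
    shorter than the longest wavelet are reflect-padded.
    """
    x = np.asarray(trace, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs >= fs_hz / 2.0):
        raise ValueError("analysis frequencies must lie below Nyquist")
    if np.any(freqs <= 0):
        raise ValueError("analysis frequencies must be positive")
    n = len(x)
    power = np.empty((len(freqs), n))
    for i, f in enumerate(freqs):
        sigma_t = n_cycles / (2.0 * np.pi * f)
        half = int(np.ceil(4.0 * sigma_t * fs_hz))
        t = np.arange(-half, half + 1) / fs_hz
        env = np.exp(-0.5 * (t / sigma_t) ** 2)
        wavelet = env * np.exp(2j * np.pi * f * t)
        # envelope-L1 normalisation with a factor 2 for the analytic signal:
        # a unit tone then yields |coefficient| = 1 at its own frequency.
        wavelet *= 2.0 / env.sum()
        pad = min(half, n - 1)
        xp = np.pad(x, pad, mode="reflect") if pad > 0 else x
        coef = sps.fftconvolve(xp, wavelet, mode="same")
        coef = coef[pad:pad + n]
        power[i] = np.abs(coef) ** 2
    return WaveletSpectrogram(power=power, freqs=freqs,
                              times=np.arange(n) / fs_hz, fs_hz=fs_hz,
                              n_cycles=n_cycles)


def compute_psd(trace: np.ndarray, fs_hz: float, notch_hz: float = 50.0,
                seg_s: float = 4.0, overlap_s: float = 0.25,
                fmax_hz: float = 100.0):
    """Welch log10-PSD on a 1/seg_s Hz grid with a pre-PSD line-noise notch.

    Hann-tapered 4-s segments with 0.25-s overlap are averaged; the output
    grid step is 0.25 Hz.  Returns ``(freqs, log10_psd, all_zero_flag)``.
    """
    x = np.asarray(trace, dtype=float)
    nseg = int(round(seg_s * fs_hz))
    if len(x) < nseg:
        raise ValueError(f"trace shorter than the {seg_s:g} s PSD segment "
                         f"({nseg} samples required)")
    if notch_hz and notch_hz < fs_hz / 2.0 and np.any(x):
        b, a = sps.iirnotch(notch_hz, Q=30.0, fs=fs_hz)
        x = sps.filtfilt(b, a, x)
    freqs, psd = sps.welch(x, fs=fs_hz, window="hann", nperseg=nseg,
                           noverlap=int(round(overlap_s * fs_hz)))
    sel = freqs <= fmax_hz
    freqs, psd = freqs[sel], psd[sel]
    all_zero = not np.any(psd > 0)
    floor = max(psd.max(), 1.0) * _POWER_FLOOR_REL if not all_zero else 1e-30
    return freqs, np.log10(np.maximum(psd, floor)), all_zero


def fit_spectral_slope(spec: WaveletSpectrogram, center_s: float | None = None,
                       half_width_s: float = 0.25,
                       fmin_hz: float = 1.0, fmax_hz: float = 200.0) -> SpectralFit:
    """Aperiodic slope/offset of log10 density vs log10 frequency.

    Power is averaged over the +-``half_width_s`` window around
    ``center_s`` (the whole spectrogram when ``center_s`` is None), divided
    by the per-frequency equivalent noise bandwidth, then regressed against
    log10 frequency by least squares.
    """
    sel_f = (spec.freqs >= fmin_hz) & (spec.freqs <= fmax_hz)
    if center_s is None:
        win = np.ones(len(spec.times), dtype=bool)
        window = (float(spec.times.mean()), float(spec.times[-1] / 2.0))
    else:
        if not (spec.times[0] <= center_s <= spec.times[-1]):
            raise ValueError("analysis window lies outside the spectrogram")
        win = np.abs(spec.times - center_s) <= half_width_s
        window = (center_s, half_width_s)
    mean_power = spec.power[np.ix_(sel_f, win)].mean(axis=1)
    density = mean_power / spec.enbw_hz()[sel_f]
    return _loglog_line(spec.freqs[sel_f], density, window)


def slope_time_course(spec: WaveletSpectrogram, times_s: np.ndarray,
                      half_width_s: float = 0.25) -> list[SpectralFit]:
    """Per-timepoint slope fits (e.g. the peri-event slope traces)."""
    return [fit_spectral_slope(spec, t, half_width_s) for t in times_s]


def _loglog_line(freqs: np.ndarray, density: np.ndarray,
                 window: tuple) -> SpectralFit:
    pos_max = density.max()
    if pos_max <= 0:
        raise ValueError("all-zero power: slope undefined")
    floor = pos_max * _POWER_FLOOR_REL
    n_floored = int(np.sum(density < floor))
    y = np.log10(np.maximum(density, floor))
    lx = np.log10(freqs)
    slope, offset = np.polyfit(lx, y, 1)
    pred = slope * lx + offset
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return SpectralFit(slope=float(slope), offset=float(offset), r2=r2,
                       window=window, n_floored=n_floored)
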