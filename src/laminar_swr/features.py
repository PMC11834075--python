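"""Per-event waveform features and the cross-layer AUC power-law analysis.

Features are computed on the filtered stratum-pyramidale (90-200 Hz) and
stratum-radiatum (2-20 Hz) traces inside each event's window: for SWR and
cSWR the window is the ripple's [start, end] (capturing every sharp wave
under a complex event); standalone R and SW use their own window, with the
other layer's simultaneous activity measured over the same span.

AUC is the trapezoidal integral of |f(x)| over the window, deliberately not
amplitude-normalised so that it reflects amplitude and duration together;
the stratum-radiatum vs stratum-pyramidale AUC relationship is summarised
by a least-squares line in log10-log10 space and compared across conditions
by a Fisher-z test on the correlation coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import hilbert, periodogram

from .spectral import morlet_spectrogram


@dataclass
class LogLogFit:
    slope: float
    intercept: float
    r: float
    n: int
    n_dropped: int = 0


def compute_auc(wave: np.ndarray, fs_hz: float) -> float:
    """Trapezoid rule on the absolute filtered event waveform, uV.s."""
    wave = np.asarray(wave, dtype=float)
    if wave.size < 2:
        raise ValueError("AUC needs at least two samples")
    return float(np.trapezoid(np.abs(wave), dx=1.0 / fs_hz))


def waveform_features(wave: np.ndarray, fs_hz: float):
    """(amplitude, mean_freq_hz, power, n_peaks) of one filtered waveform.

    amplitude = max |Hilbert envelope|; mean frequency = first spectral
    moment of the one-sided periodogram; power = sum(f^2)/N (signal energy
    over duration); peaks = samples strictly above both neighbours, no
    prominence requirement.
    """
    x = np.asarray(wave, dtype=float)
    if x.size < 3:
        raise ValueError("waveform too short")
    amplitude = float(np.max(np.abs(hilbert(x))))
    freqs, psd = periodogram(x, fs=fs_hz)
    total = psd.sum()
    mean_freq = float((freqs * psd).sum() / total) if total > 0 else 0.0
    power = float(np.sum(x ** 2) / x.size)
    interior = x[1:-1]
    n_peaks = int(np.sum((interior > x[:-2]) & (interior > x[2:])))
    return amplitude, mean_freq, power, n_peaks


def sw_frequency(sr_trace: np.ndarray, fs_hz: float, peak_s: float,
                 start_s: float, end_s: float,
                 context_s: float = 6.0) -> tuple[float, bool]:
    """Sharp-wave frequency from a Morlet spectrogram of a 6-s context.

    The wavelet power between the event's start and end is summed over
    time per frequency, normalised to unit sum and dotted with the 1-200 Hz
    frequency vector.  Returns ``(freq_hz, degenerate_flag)``; an all-zero
    window yields (0.0, True).
    """
    x = np.asarray(sr_trace, dtype=float)
    n = len(x)
    i_peak = int(round(peak_s * fs_hz))
    if not (0 <= i_peak < n):
        raise ValueError("event peak lies outside the trace")
    half = int(round(context_s / 2.0 * fs_hz))
    i0, i1 = i_peak - half, i_peak + half
    pad_lo, pad_hi = max(0, -i0), max(0, i1 - n)
    seg = x[max(i0, 0):min(i1, n)]
    if pad_lo or pad_hi:
        seg = np.pad(seg, (pad_lo, pad_hi), mode="reflect")
    spec = morlet_spectrogram(seg, fs_hz)
    t0 = (i0 / fs_hz)
    sel_t = (spec.times + t0 >= start_s) & (spec.times + t0 <= end_s)
    if not sel_t.any():
        raise ValueError("event window empty at this sampling rate")
    # divide by the per-frequency equivalent noise bandwidth so the
    # fixed-cycle wavelet's growing bandwidth does not overweight high
    # frequencies in the weighted mean
    marginal = np.abs(spec.power[:, sel_t].sum(axis=1)) / spec.enbw_hz()
    total = marginal.sum()
    if total == 0:
        return 0.0, True
    return float((marginal / total) @ spec.freqs), False


def event_feature_table(events: pd.DataFrame, sp_filtered: np.ndarray,
                        sr_filtered: np.ndarray, sr_raw: np.ndarray,
                        fs_hz: float) -> pd.DataFrame:
    """Tidy per-event, per-layer feature rows keyed by event_id.

    ``sp_filtered``/``sr_filtered`` are the 90-200 Hz and 2-20 Hz traces;
    ``sr_raw`` is the unfiltered stratum-radiatum trace used only for the
    wavelet-based sharp-wave frequency of SW-bearing events.
    """
    rows = []
    n = len(sp_filtered)
    for ev in events.itertuples(index=False):
        i0 = max(0, int(round(ev.start_s * fs_hz)))
        i1 = min(n, int(round(ev.end_s * fs_hz)) + 1)
        if i1 - i0 < 3:
            continue
        row = {"event_id": ev.event_id, "type": ev.type,
               "duration_ms": (ev.end_s - ev.start_s) * 1000.0}
        for layer, trace in (("SP", sp_filtered), ("SR", sr_filtered)):
            seg = trace[i0:i1]
            amp, mfreq, pwr, npk = waveform_features(seg, fs_hz)
            row[f"{layer.lower()}_amplitude_uv"] = amp
            row[f"{layer.lower()}_mean_freq_hz"] = mfreq
            row[f"{layer.lower()}_power_uv2"] = pwr
            row[f"{layer.lower()}_n_peaks"] = npk
            row[f"{layer.lower()}_auc_uvs"] = compute_auc(seg, fs_hz)
        if ev.type in ("SW", "SWR", "cSWR"):
            f, degenerate = sw_frequency(sr_raw, fs_hz, ev.peak_s,
                                         ev.start_s, ev.end_s)
            row["sw_freq_hz"] = f
            row["sw_freq_degenerate"] = degenerate
        else:
            row["sw_freq_hz"] = np.nan
            row["sw_freq_degenerate"] = False
        rows.append(row)
    return pd.DataFrame(rows)


def loglog_fit(x: np.ndarray, y: np.ndarray) -> LogLogFit:
    """Least-squares line of log10(y) on log10(x); non-positive pairs dropped."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = (x > 0) & (y > 0)
    n_dropped = int(np.sum(~keep))
    lx, ly = np.log10(x[keep]), np.log10(y[keep])
    if len(lx) < 3:
        raise ValueError("need at least 3 positive pairs for a log-log fit")
    res = stats.linregress(lx, ly)
    return LogLogFit(slope=float(res.slope), intercept=float(res.intercept),
                     r=float(res.rvalue), n=len(lx), n_dropped=n_dropped)


def compare_correlation_slopes(rA: float, nA: int, rB: float, nB: int):
    """Fisher-z test of two correlation coefficients -> (z, p)."""
    for r, n in ((rA, nA), (rB, nB)):
        if abs(r) >= 1.0:
            raise ValueError("|r| must be < 1 for the Fisher transform")
        if n <= 3:
            raise ValueError("need n > 3 per sample")
    z = (np.arctanh(rA) - np.arctanh(rB)) / \
        np.sqrt(1.0 / (nA - 3) + 1.0 / (nB - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def select_median_events(events: pd.DataFrame, k: int,
                         amplitude_col: str | None = None) -> pd.DataFrame:
    """The k events closest in amplitude to the median amplitude.

    Ripple-bearing types are ranked on the stratum-pyramidale amplitude and
    standalone sharp waves on the stratum-radiatum amplitude unless a column
    is given explicitly; ties break toward the earlier peak.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if events.empty:
        return events
    if amplitude_col is None:
        amplitude_col = ("sr_amplitude_uv"
                         if set(events["type"]) == {"SW"}
                         else "sp_amplitude_uv")
    amp = events[amplitude_col].to_numpy(dtype=float)
    dist = np.abs(amp - np.median(amp))
    order = np.lexsort((events["peak_s"].to_numpy()
                        if "peak_s" in events else np.arange(len(events)),
                        dist))
    return events.iloc[order[:k]].sort_index()


def density_contours(x: np.ndarray, y: np.ndarray, n_levels: int = 3,
                     grid_n: int = 128, zscore: bool = False):
    """Bivariate Gaussian-KDE grid with equal-mass contour levels.

    Returns ``(xx, yy, density, levels)`` with ``levels`` ascending:
    the region with density >= ``levels[i]`` holds mass
    (n_levels - i) / n_levels, so the last level is the innermost contour
    enclosing 1/n_levels of the mass.  ``zscore=True`` standardises the
    density grid (the 6-level type-mixed display variant).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 points")
    try:
        kde = stats.gaussian_kde(np.vstack([x, y]))  # Scott's rule bandwidth
    except np.linalg.LinAlgError as err:
        raise ValueError("degenerate (collinear) data") from err
    pad_x = 0.15 * (x.max() - x.min() + 1e-12)
    pad_y = 0.15 * (y.max() - y.min() + 1e-12)
    gx = np.linspace(x.min() - pad_x, x.max() + pad_x, grid_n)
    gy = np.linspace(y.min() - pad_y, y.max() + pad_y, grid_n)
    xx, yy = np.meshgrid(gx, gy)
    dens = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
    cell = (gx[1] - gx[0]) * (gy[1] - gy[0])
    flat = np.sort(dens.ravel())[::-1]
    cum = np.cumsum(flat) * cell
    total = cum[-1]
    levels = []
    for i in range(1, n_levels + 1):
        target = total * i / n_levels
        j = int(np.searchsorted(cum, min(target, total * (1 - 1e-12))))
        levels.append(float(flat[min(j, len(flat) - 1)]))
    levels = levels[::-1]
    out = (dens - dens.mean()) / dens.std() if zscore else dens
    return xx, yy, out, levels
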