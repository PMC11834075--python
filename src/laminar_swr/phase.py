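"""Slow-oscillation phase coupling, delta waves, bout-edge rates, ratios.

The prefrontal trace is band-passed 0.5-4 Hz, NonREM-like bouts are
concatenated, and the analytic-signal angle gives each sample a phase in
[0, 360) under the cosine convention (signal peak = 0 deg, trough =
180 deg, so the down-to-upstate transition of a cortical slow oscillation
sits near the ascending zero crossing at 270 deg).  Hippocampal event
peaks are then assigned the phase of the sample they fall on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, hilbert, sosfiltfilt

from .core import NREM, Hypnogram


@dataclass
class DeltaWaveParams:
    band_hz: tuple = (1.0, 6.0)
    min_dur_ms: float = 150.0
    max_dur_ms: float = 550.0
    peak_threshold_uv: float | None = None   # default: +2 SD
    trough_threshold_uv: float | None = None  # default: -1.5 SD
    peak_sd: float = 2.0
    trough_sd: float = 1.5


def compute_so_phase(pfc_trace: np.ndarray, hypnogram: Hypnogram,
                     fs_hz: float, band_hz: tuple = (0.5, 4.0)):
    """Per-sample slow-oscillation phase over NonREM-like bouts.

    Returns ``(phase_deg, covered_mask)``: phase in [0, 360) where
    ``covered_mask`` is True (NonREM-like samples), NaN elsewhere.  The
    Hilbert transform runs on the concatenated NonREM-like signal, exactly
    as the bouts are analysed, then phases are split back per bout.
    """
    x = np.asarray(pfc_trace, dtype=float)
    bouts = hypnogram.bouts(NREM)
    if not bouts:
        raise ValueError("no NonREM-like bouts in the hypnogram")
    sos = butter(3, band_hz, btype="band", fs=fs_hz, output="sos")
    filtered = sosfiltfilt(sos, x)
    spans = [(int(s0 * fs_hz), min(int(s1 * fs_hz), len(x)))
             for _, s0, s1 in bouts]
    concat = np.concatenate([filtered[a:b] for a, b in spans])
    angle = np.angle(hilbert(concat))
    phase_concat = np.degrees(angle) % 360.0
    phase = np.full(len(x), np.nan)
    covered = np.zeros(len(x), dtype=bool)
    off = 0
    for a, b in spans:
        phase[a:b] = phase_concat[off:off + (b - a)]
        covered[a:b] = True
        off += b - a
    return phase, covered


def event_phase_stats(events: pd.DataFrame, phase_deg: np.ndarray,
                      fs_hz: float):
    """Phase of each event peak plus per-type circular summaries.

    Returns ``(phase_table, summary)``; events whose peak has no phase
    (outside NonREM-like coverage) are excluded, their count reported in
    the summary attrs.
    """
    rows, n_excluded = [], 0
    for ev in events.itertuples(index=False):
        i = int(round(ev.peak_s * fs_hz))
        if i < 0 or i >= len(phase_deg) or np.isnan(phase_deg[i]):
            n_excluded += 1
            continue
        rows.append({"event_id": ev.event_id, "type": ev.type,
                     "phase_deg": float(phase_deg[i])})
    table = pd.DataFrame(rows, columns=["event_id", "type", "phase_deg"])
    summaries = []
    for etype, grp in table.groupby("type"):
        rad = np.radians(grp["phase_deg"].to_numpy())
        vec = np.exp(1j * rad).mean()
        summaries.append({"type": etype, "n": len(grp),
                          "circ_mean_deg": float(np.degrees(np.angle(vec)) % 360.0),
                          "resultant_length": float(np.abs(vec))})
    summary = pd.DataFrame(summaries,
                           columns=["type", "n", "circ_mean_deg",
                                    "resultant_length"])
    summary.attrs["n_excluded"] = n_excluded
    return table, summary


def detect_delta_waves(pfc_trace: np.ndarray, fs_hz: float,
                       params: DeltaWaveParams | None = None,
                       bin_fn=None):
    """Cortical delta waves: biphasic 1-6 Hz deflections, 150-550 ms.

    Candidates are zero-crossing-delimited segments of the filtered trace
    containing a positive peak followed by a trough; kept when the peak and
    trough clear their thresholds and the duration lies in bounds.
    Returns ``(delta_table, counts_per_bin)``.
    """
    p = params or DeltaWaveParams()
    x = np.asarray(pfc_trace, dtype=float)
    sos = butter(3, p.band_hz, btype="band", fs=fs_hz, output="sos")
    f = sosfiltfilt(sos, x)
    sd = float(np.std(f))
    if sd == 0:
        return (pd.DataFrame(columns=["start_s", "peak_s", "trough_s",
                                      "end_s", "duration_ms", "bin_index"]),
                pd.Series(dtype=int))
    peak_thr = p.peak_threshold_uv if p.peak_threshold_uv is not None \
        else p.peak_sd * sd
    trough_thr = p.trough_threshold_uv if p.trough_threshold_uv is not None \
        else -p.trough_sd * sd
    if peak_thr <= 0 or trough_thr >= 0:
        raise ValueError("degenerate delta-wave thresholds")

    # zero crossings of the filtered trace delimit candidate waves
    sign = np.signbit(f)
    up = np.flatnonzero(~sign[1:] & sign[:-1]) + 1    # - -> + crossings
    rows = []
    for a, c in zip(up[:-1], up[1:]):
        seg = f[a:c]
        down_rel = np.flatnonzero(np.signbit(seg[1:]) & ~np.signbit(seg[:-1]))
        if len(down_rel) == 0:
            continue
        mid = a + int(down_rel[0]) + 1
        i_peak = a + int(np.argmax(f[a:mid])) if mid > a else a
        i_trough = mid + int(np.argmin(f[mid:c])) if c > mid else mid
        dur_ms = (c - a) / fs_hz * 1000.0
        if (f[i_peak] >= peak_thr and f[i_trough] <= trough_thr and
                p.min_dur_ms <= dur_ms <= p.max_dur_ms):
            rows.append({"start_s": a / fs_hz, "peak_s": i_peak / fs_hz,
                         "trough_s": i_trough / fs_hz, "end_s": c / fs_hz,
                         "duration_ms": dur_ms,
                         "bin_index": bin_fn(a / fs_hz) if bin_fn else 0})
    table = pd.DataFrame(rows, columns=["start_s", "peak_s", "trough_s",
                                        "end_s", "duration_ms", "bin_index"])
    counts = table.groupby("bin_index").size() if len(table) else \
        pd.Series(dtype=int)
    return table, counts


def bout_edge_ripple_rate(events: pd.DataFrame, hypnogram: Hypnogram,
                          min_bout_min: float = 15.0,
                          edge_frac: float = 0.10) -> pd.DataFrame:
    """Ripple rate in the first and last fraction of long NonREM-like bouts.

    Bouts shorter than ``min_bout_min`` are excluded; the rate is the count
    of ripple-bearing event peaks in each edge segment divided by the
    segment duration.
    """
    peaks = events.loc[events["type"].isin(["R", "SWR", "cSWR"]),
                       "peak_s"].to_numpy()
    rows = []
    for bout_id, (_, s0, s1) in enumerate(hypnogram.bouts(NREM)):
        dur = s1 - s0
        if dur <= min_bout_min * 60.0:
            continue
        edge = dur * edge_frac
        n_start = int(np.sum((peaks >= s0) & (peaks < s0 + edge)))
        n_end = int(np.sum((peaks >= s1 - edge) & (peaks < s1)))
        rows.append({"bout_id": bout_id, "bout_start_s": s0,
                     "bout_duration_s": dur,
                     "start_rate_hz": n_start / edge,
                     "end_rate_hz": n_end / edge})
    return pd.DataFrame(rows, columns=["bout_id", "bout_start_s",
                                       "bout_duration_s", "start_rate_hz",
                                       "end_rate_hz"])


def long_short_ratio(events: pd.DataFrame, cutoff_ms: float = 100.0):
    """count(duration > cutoff) / count(duration <= cutoff) for ripples.

    Computed over ripple-bearing events; returns ``(ratio, n_long,
    n_short)`` with ratio NaN when the short count is zero.
    """
    if cutoff_ms <= 0:
        raise ValueError("cutoff_ms must be positive")
    rip = events[events["type"].isin(["R", "SWR", "cSWR"])]
    dur_ms = (rip["end_s"] - rip["start_s"]).to_numpy() * 1000.0
    n_long = int(np.sum(dur_ms > cutoff_ms))
    n_short = int(np.sum(dur_ms <= cutoff_ms))
    ratio = n_long / n_short if n_short > 0 else float("nan")
    return ratio, n_long, n_short
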