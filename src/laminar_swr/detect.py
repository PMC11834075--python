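"""Hippocampal event detection and R/SW/SWR/cSWR classification.

Ripples are detected on the 90-200 Hz filtered stratum-pyramidale trace and
sharp waves on the 2-20 Hz filtered stratum-radiatum trace, independently.
A ripple's detection magnitude is the Hilbert envelope of the filtered
trace: a 90-200 Hz oscillation cannot itself stay above a voltage level for
50 ms, so the amplitude criterion is applied to the envelope (a 10 ms RMS
magnitude is available as an alternative).  Sharp waves are voltage troughs
of the filtered trace below mean - k.SD.

Co-occurrence is classified per ripple by counting sharp-wave overlaps via
two non-mutually-exclusive endpoint-containment cases — the sharp wave's
end, or its start, falling inside the ripple's [start, end].  0, 1 and >=2
overlaps give R, SWR and cSWR; sharp waves overlapping no ripple are SW.
Note the literal rule's edge: a sharp wave strictly containing a ripple has
neither endpoint inside it and therefore counts as NO overlap; an opt-in
``mode="intersection"`` treats any interval intersection as overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .core import Interval, empty_events_frame

RIPPLE_BAND = (90.0, 200.0)
SW_BAND = (2.0, 20.0)


@dataclass
class DetectionParams:
    ripple_band: tuple = RIPPLE_BAND
    sw_band: tuple = SW_BAND
    threshold_sd: float = 5.0
    min_dur_ms: float = 50.0
    merge_ms: float = 80.0
    boundary_frac: float = 0.5
    magnitude: str = "hilbert"  # or "rms"
    rms_window_ms: float = 10.0

    def __post_init__(self) -> None:
        if self.threshold_sd < 0:
            raise ValueError("threshold_sd must be >= 0")
        if not (0 < self.boundary_frac <= 1):
            raise ValueError("boundary_frac must lie in (0, 1]")
        for band in (self.ripple_band, self.sw_band):
            if band[0] >= band[1]:
                raise ValueError("bands must be ordered (lo, hi)")


def envelope(filtered: np.ndarray, fs_hz: float,
             params: DetectionParams | None = None) -> np.ndarray:
    """Detection magnitude of a band-passed trace."""
    p = params or DetectionParams()
    if p.magnitude == "hilbert":
        return np.abs(hilbert(filtered))
    w = max(int(round(p.rms_window_ms / 1000.0 * fs_hz)), 1)
    kernel = np.ones(w) / w
    return np.sqrt(np.convolve(filtered ** 2, kernel, mode="same"))


def estimate_threshold(magnitude: np.ndarray, threshold_sd: float = 5.0,
                       boundary_frac: float = 0.5,
                       valid: np.ndarray | None = None):
    """(detect_level, boundary_level) = mean + k.SD and its fraction.

    ``valid`` restricts the baseline to artifact-free (and, in the pipeline,
    NonREM-like) samples.
    """
    m = magnitude if valid is None else magnitude[valid]
    if m.size == 0:
        raise ValueError("no valid samples for threshold estimation")
    sd = float(np.std(m))
    if sd == 0:
        raise ValueError("zero-variance magnitude: threshold undefined")
    detect = float(np.mean(m)) + threshold_sd * sd
    return detect, boundary_frac * detect


def _contiguous_spans(mask: np.ndarray):
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))  # half-open sample spans


def detect_ripples(sp_filtered: np.ndarray, fs_hz: float,
                   params: DetectionParams | None = None,
                   valid: np.ndarray | None = None) -> list[Interval]:
    """Ripple intervals from the band-passed stratum-pyramidale trace.

    Supra-threshold cores >= ``min_dur_ms`` are kept, edges are extended
    outward to the boundary-level (half-threshold) crossings, events closer
    than ``merge_ms`` are merged, and the peak is the envelope maximum.
    """
    p = params or DetectionParams()
    mag = envelope(sp_filtered, fs_hz, p)
    if not np.any(mag):
        return []
    detect, boundary = estimate_threshold(mag, p.threshold_sd,
                                          p.boundary_frac, valid)
    min_n = int(round(p.min_dur_ms / 1000.0 * fs_hz))
    cores = [(a, b) for a, b in _contiguous_spans(mag >= detect)
             if b - a >= min_n]
    if not cores:
        return []
    below = mag < boundary
    spans = []
    n = len(mag)
    for a, b in cores:
        lo = a
        while lo > 0 and not below[lo - 1]:
            lo -= 1
        hi = b
        while hi < n and not below[hi]:
            hi += 1
        spans.append((lo, hi))
    # merge events with gaps below the closeness threshold
    merge_n = int(round(p.merge_ms / 1000.0 * fs_hz))
    merged = [spans[0]]
    for a, b in spans[1:]:
        if a - merged[-1][1] < merge_n:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        elif a < merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    out = []
    for a, b in merged:
        peak = a + int(np.argmax(mag[a:b]))
        out.append(Interval(a / fs_hz, peak / fs_hz, (b - 1) / fs_hz))
    return out


def detect_sharp_waves(sr_filtered: np.ndarray, fs_hz: float,
                       params: DetectionParams | None = None,
                       valid: np.ndarray | None = None) -> list[Interval]:
    """Sharp-wave intervals: troughs of the 2-20 Hz trace below mean - k.SD."""
    p = params or DetectionParams()
    x = np.asarray(sr_filtered, dtype=float)
    base = x if valid is None else x[valid]
    sd = float(np.std(base))
    if sd == 0:
        return []
    level = float(np.mean(base)) - p.threshold_sd * sd
    out = []
    for a, b in _contiguous_spans(x < level):
        peak = a + int(np.argmin(x[a:b]))
        out.append(Interval(a / fs_hz, peak / fs_hz, (b - 1) / fs_hz))
    return out


# ---------------------------------------------------------------------------
# Co-occurrence classification
# ---------------------------------------------------------------------------

def _overlaps(ripple: Interval, sw: Interval, mode: str) -> bool:
    if mode == "literal":
        return (ripple.start_s <= sw.end_s <= ripple.end_s or
                ripple.start_s <= sw.start_s <= ripple.end_s)
    if mode == "intersection":
        return max(ripple.start_s, sw.start_s) <= min(ripple.end_s, sw.end_s)
    raise ValueError(f"unknown overlap mode {mode!r}")


def classify_events(ripples, sws, hypnogram=None, bin_fn=None,
                    mode: str = "literal") -> pd.DataFrame:
    """Classify detections into R / SW / SWR / cSWR event records.

    ``ripples`` and ``sws`` are Interval lists (or (start, peak, end)
    tuples) on a common time base.  Each ripple is typed by its sharp-wave
    overlap count; sharp waves belonging to no ripple become standalone SW
    events.  Records are annotated with the hypnogram state at the peak and
    the 45-min bin index when those are supplied.
    """
    ripples = _as_intervals(ripples, "ripple")
    sws = _as_intervals(sws, "sharp wave")

    sw_used = [False] * len(sws)
    rows = []
    for r in ripples:
        hits = [j for j, s in enumerate(sws) if _overlaps(r, s, mode)]
        for j in hits:
            sw_used[j] = True
        k = len(hits)
        etype = "R" if k == 0 else ("SWR" if k == 1 else "cSWR")
        rows.append((etype, r.start_s, r.peak_s, r.end_s, k))
    for j, s in enumerate(sws):
        if not sw_used[j]:
            rows.append(("SW", s.start_s, s.peak_s, s.end_s, 0))

    rows.sort(key=lambda t: t[1])
    if not rows:
        return empty_events_frame()
    df = pd.DataFrame(rows, columns=["type", "start_s", "peak_s", "end_s",
                                     "n_sw_overlaps"])
    df.insert(0, "event_id", np.arange(len(df)))
    df["state"] = [hypnogram.label_at(t) for t in df["peak_s"]] \
        if hypnogram is not None else "unknown"
    df["bin_index"] = [bin_fn(t) for t in df["peak_s"]] \
        if bin_fn is not None else 0
    return df


def _as_intervals(items, what: str) -> list[Interval]:
    out = []
    seen = set()
    for it in items:
        iv = it if isinstance(it, Interval) else Interval(*it)
        key = (iv.start_s, iv.end_s)
        if key in seen:
            warnings.warn(f"duplicate {what} interval dropped: {key}")
            continue
        seen.add(key)
        out.append(iv)
    return sorted(out, key=lambda iv: iv.start_s)
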