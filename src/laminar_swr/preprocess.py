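"""Preprocessing: anti-alias downsampling, artifact blanking, trim and bin.

All downstream stages consume the output of this module: a 600 Hz,
artifact-blanked recording with the first minutes discarded and a 45-min
bin index function.  Band-pass filtering needed by the detectors must be
applied BEFORE blanking (blanking introduces steps that would otherwise
ring through a band-pass filter); the pipeline enforces that ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import LaminarRecording

DEFAULT_BUILDUP_S = 0.5
DEFAULT_WASHOUT_S = 3.5
# The power-spectra preprocessing of the same recordings used a 3.33 s
# washout; available as an explicit override.
PSD_WASHOUT_S = 10.0 / 3.0


@dataclass
class ArtifactSet:
    """Sorted, merged half-open [start_s, end_s) intervals to blank."""

    intervals: list

    def __post_init__(self) -> None:
        self.intervals = merge_intervals(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)


def merge_intervals(intervals) -> list:
    ivs = sorted((float(a), float(b)) for a, b in intervals)
    out: list[tuple[float, float]] = []
    for a, b in ivs:
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def antialias_downsample(rec: LaminarRecording, target_fs: float,
                         cutoff_hz: float = 300.0) -> LaminarRecording:
    """Zero-phase 3rd-order Butterworth low-pass, then integer decimation."""
    factor = rec.fs_hz / target_fs
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("target_fs must divide fs_hz (integer decimation)")
    factor = int(round(factor))
    if cutoff_hz > target_fs / 2.0:
        raise ValueError("anti-alias cutoff must not exceed the target Nyquist")
    if factor == 1:
        return rec
    sos = signal.butter(3, cutoff_hz, btype="low", fs=rec.fs_hz, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples, axis=1)
    out = filtered[:, ::factor]
    return LaminarRecording(
        samples=out, fs_hz=target_fs, channel_labels=rec.channel_labels,
        depth_um=rec.depth_um, layer_map=rec.layer_map,
        start_clock_s=rec.start_clock_s,
        valid_mask=rec.valid_mask[::factor].copy())


def detect_artifacts(traces: np.ndarray, fs_hz: float,
                     threshold_uv: float | None = None,
                     threshold_sd: float = 8.0) -> ArtifactSet:
    """Flag samples where the summed absolute signal crosses a threshold.

    ``traces`` is channels x time (one channel allowed as 1-D).  With no
    explicit ``threshold_uv`` the level defaults to mean + ``threshold_sd``
    standard deviations of the summed-absolute signal, a reproducible stand-in
    for per-animal visual threshold setting.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    total = np.sum(np.abs(traces), axis=0)
    if threshold_uv is None:
        threshold_uv = float(np.mean(total) + threshold_sd * np.std(total))
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    flagged = total > threshold_uv
    intervals = []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], flagged.view(np.int8), [0]))))
    for i0, i1 in zip(idx[::2], idx[1::2]):
        intervals.append((i0 / fs_hz, i1 / fs_hz))
    return ArtifactSet(intervals)


def blank_artifacts(rec: LaminarRecording, artifacts: ArtifactSet,
                    buildup_s: float = DEFAULT_BUILDUP_S,
                    washout_s: float = DEFAULT_WASHOUT_S) -> LaminarRecording:
    """Replace each artifact plus buildup/washout with the clean mean.

    Per channel, samples in [start - buildup, end + washout) are replaced by
    the mean of the remaining (unblanked, previously valid) samples; the
    valid mask is cleared over the blanked spans.
    """
    if buildup_s < 0 or washout_s < 0:
        raise ValueError("buildup_s and washout_s must be >= 0")
    n = rec.n_samples
    blank = np.zeros(n, dtype=bool)
    for a, b in artifacts.intervals:
        i0 = max(0, int(math.floor((a - buildup_s) * rec.fs_hz)))
        i1 = min(n, int(math.ceil((b + washout_s) * rec.fs_hz)))
        blank[i0:i1] = True
    keep = rec.valid_mask & ~blank
    if not keep.any():
        raise ValueError("blanking would remove the entire recording")
    out = rec.samples.copy()
    means = out[:, keep].mean(axis=1)
    out[:, blank] = means[:, None]
    return LaminarRecording(
        samples=out, fs_hz=rec.fs_hz, channel_labels=rec.channel_labels,
        depth_um=rec.depth_um, layer_map=rec.layer_map,
        start_clock_s=rec.start_clock_s, valid_mask=keep)


def trim_and_bin(rec: LaminarRecording, discard_min: float = 15.0,
                 bin_min: float = 45.0):
    """Drop the initial instability period and return a 45-min bin mapper.

    Returns ``(trimmed_recording, bin_fn)`` with ``bin_fn(t) =
    floor(t / bin_min)`` on the post-trim time axis.
    """
    discard_s = discard_min * 60.0
    if rec.duration_s <= discard_s:
        raise ValueError("recording shorter than the discard window")
    i0 = int(round(discard_s * rec.fs_hz))
    trimmed = LaminarRecording(
        samples=rec.samples[:, i0:], fs_hz=rec.fs_hz,
        channel_labels=rec.channel_labels, depth_um=rec.depth_um,
        layer_map=rec.layer_map, start_clock_s=rec.start_clock_s + discard_s,
        valid_mask=rec.valid_mask[i0:].copy())

    bin_s = bin_min * 60.0

    def bin_fn(t_s: float) -> int:
        return int(np.floor(t_s / bin_s))

    return trimmed, bin_fn


def align_recordings(recordings: list[LaminarRecording]) -> list[LaminarRecording]:
    """Align recordings by time-of-day with masked head/tail padding.

    Padding samples are zero-valued but excluded from the valid mask, so no
    numeric sentinel ever enters an analysis.
    """
    if not recordings:
        return []
    fs = recordings[0].fs_hz
    if any(r.fs_hz != fs for r in recordings):
        raise ValueError("alignment requires a common sampling rate")
    t0 = min(r.start_clock_s for r in recordings)
    t1 = max(r.start_clock_s + r.duration_s for r in recordings)
    n_total = int(round((t1 - t0) * fs))
    out = []
    for r in recordings:
        head = int(round((r.start_clock_s - t0) * fs))
        tail = n_total - head - r.n_samples
        samples = np.pad(r.samples, ((0, 0), (head, max(tail, 0))))
        mask = np.pad(r.valid_mask, (head, max(tail, 0)))
        out.append(LaminarRecording(
            samples=samples[:, :n_total], fs_hz=fs,
            channel_labels=r.channel_labels, depth_um=r.depth_um,
            layer_map=r.layer_map, start_clock_s=t0,
            valid_mask=mask[:n_total]))
    return out


def bandpass(traces: np.ndarray, fs_hz: float, lo_hz: float, hi_hz: float,
             order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass shared by every detection stage."""
    sos = signal.butter(order, (lo_hz, hi_hz), btype="band", fs=fs_hz,
                        output="sos")
    return signal.sosfiltfilt(sos, traces, axis=-1)
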