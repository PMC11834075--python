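"""Current source density and AVREC laminar profiles.

CSD is the discrete second spatial derivative of the laminar potential,
CSD_i(t) = Theta_{i-1}(t) - 2 Theta_i(t) + Theta_{i+1}(t), computed for
interior channels only (no boundary padding; an opt-in Vaknin-style edge
duplication is available).  Spacing is treated as unit, matching arbitrary
CSD units; physical scaling by 1/h^2 is a caller-side multiplication.
AVREC — the mean of |CSD| over channels — summarises total transmembrane
current strength over time, and delta-AVREC expresses each event type's
layer AVREC relative to the SWR reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import LaminarRecording


@dataclass
class LaminarWindow:
    theta: np.ndarray          # channels x samples, depth-ordered, raw LFP
    fs_hz: float
    event_type: str
    peak_s: float
    channel_labels: list


@dataclass
class CSDProfile:
    csd: np.ndarray            # (channels - 2) x samples
    fs_hz: float
    event_type: str
    channel_labels: list       # interior channels


def extract_peri_event_windows(rec: LaminarRecording, events: pd.DataFrame,
                               window_s: float = 6.0,
                               channels: list[int] | None = None):
    """Raw 6-s windows centred on each event peak.

    For SWR/cSWR the stored peak already is the pyramidal-layer (ripple)
    peak.  Events too close to the recording edges are skipped; returns
    ``(windows, n_skipped)``.
    """
    if channels is None:
        channels = [i for i, lab in enumerate(rec.channel_labels)
                    if rec.layer_map.get(lab) in ("SO", "SP", "SR", "SLM")]
    half = int(round(window_s / 2.0 * rec.fs_hz))
    labels = [rec.channel_labels[i] for i in channels]
    out, skipped = [], 0
    for ev in events.itertuples(index=False):
        c = int(round(ev.peak_s * rec.fs_hz))
        if c - half < 0 or c + half + 1 > rec.n_samples:
            skipped += 1
            continue
        out.append(LaminarWindow(
            theta=rec.samples[np.ix_(channels, range(c - half, c + half + 1))],
            fs_hz=rec.fs_hz, event_type=ev.type, peak_s=ev.peak_s,
            channel_labels=labels))
    return out, skipped


def compute_csd(window: LaminarWindow, vaknin: bool = False) -> CSDProfile:
    """Second spatial difference across channels (unit spacing)."""
    theta = np.asarray(window.theta, dtype=float)
    if vaknin:
        theta = np.vstack([theta[:1], theta, theta[-1:]])
        labels = list(window.channel_labels)
    else:
        labels = list(window.channel_labels[1:-1])
    if theta.shape[0] < 3:
        raise ValueError("CSD needs at least 3 channels")
    csd = theta[:-2] - 2.0 * theta[1:-1] + theta[2:]
    return CSDProfile(csd=csd, fs_hz=window.fs_hz,
                      event_type=window.event_type, channel_labels=labels)


def compute_avrec(profile: CSDProfile,
                  layer_map: dict | None = None):
    """AVREC(t) = mean_i |CSD_i(t)|, overall and optionally per layer.

    Returns the overall trace when no layer map is given, otherwise
    ``(overall, {layer: trace})`` over layers that own interior channels.
    """
    if profile.csd.size == 0:
        raise ValueError("empty CSD profile")
    rect = np.abs(profile.csd)
    overall = rect.mean(axis=0)
    if layer_map is None:
        return overall
    per_layer = {}
    for layer in ("SO", "SP", "SR", "SLM"):
        idx = [i for i, lab in enumerate(profile.channel_labels)
               if layer_map.get(lab) == layer]
        if idx:
            per_layer[layer] = rect[idx].mean(axis=0)
    return overall, per_layer


def layer_avrec_table(windows: list[LaminarWindow], layer_map: dict,
                      summary_half_width_s: float = 0.5) -> pd.DataFrame:
    """Mean per-layer AVREC per event type.

    The scalar summary averages the AVREC trace over the peri-event core
    (+- ``summary_half_width_s`` around the window centre), where the
    event-locked transmembrane currents live.
    """
    rows = []
    for w in windows:
        prof = compute_csd(w)
        _, per_layer = compute_avrec(prof, layer_map)
        n = prof.csd.shape[1]
        half = int(round(summary_half_width_s * prof.fs_hz))
        sl = slice(max(0, n // 2 - half), min(n, n // 2 + half + 1))
        for layer, trace in per_layer.items():
            rows.append({"type": w.event_type, "layer": layer,
                         "avrec": float(trace[sl].mean())})
    df = pd.DataFrame(rows)
    return df.groupby(["type", "layer"], as_index=False)["avrec"].mean()


def delta_avrec(avrec_by_type: pd.DataFrame,
                reference_type: str = "SWR") -> pd.DataFrame:
    """Per-type, per-layer AVREC relative to the reference event type.

    ``abs_delta`` = layer mean AVREC(type) - layer mean AVREC(reference);
    ``norm_delta`` divides that by the reference layer mean (NaN-flagged
    when the reference mean is zero).  The opposite subtraction orientation
    is emitted as ``abs_delta_ref_minus_type`` for completeness.
    """
    ref = avrec_by_type[avrec_by_type["type"] == reference_type]
    if ref.empty:
        raise ValueError(f"reference type {reference_type!r} absent")
    ref_by_layer = dict(zip(ref["layer"], ref["avrec"]))
    rows = []
    for r in avrec_by_type.itertuples(index=False):
        if r.layer not in ref_by_layer:
            continue
        base = ref_by_layer[r.layer]
        d = r.avrec - base
        rows.append({"type": r.type, "layer": r.layer,
                     "abs_delta": d,
                     "abs_delta_ref_minus_type": -d,
                     "norm_delta": d / base if base != 0 else np.nan})
    return pd.DataFrame(rows)
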