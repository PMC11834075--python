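"""Shared containers and on-disk formats.

The pipeline's canonical objects: a multi-channel laminar recording, a
per-epoch hypnogram, tables of detected events, and the raw-binary +
JSON-sidecar recording format every stage reads and writes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

HPC_LAYERS = ("SO", "SP", "SR", "SLM")
PFC_LABELS = ("PFC_shallow", "PFC_deep")
EVENT_TYPES = ("R", "SW", "SWR", "cSWR")

NREM = "NREM_like"
REM = "REM_like"
EXCLUDED = "excluded"


@dataclass
class LaminarRecording:
    """Channels x samples potential matrix with laminar metadata.

    ``samples`` is in microvolts, channels ordered shallow -> deep
    (strictly increasing ``depth_um``). ``layer_map`` assigns each channel
    label to one of SO/SP/SR/SLM/PFC_shallow/PFC_deep/other.
    ``valid_mask`` marks samples usable for analysis; alignment padding and
    blanked artifacts are excluded there, never encoded as numeric
    sentinels in ``samples``.
    """

    samples: np.ndarray
    fs_hz: float
    channel_labels: list[str]
    depth_um: np.ndarray
    layer_map: dict[str, str]
    start_clock_s: float = 0.0
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2:
            raise ValueError("samples must be channels x time")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("one label per channel required")
        self.depth_um = np.asarray(self.depth_um, dtype=float)
        if np.any(np.diff(self.depth_um) <= 0):
            raise ValueError("depth_um must increase strictly with channel index")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.samples.shape[1], dtype=bool)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def channels_of_layer(self, layer: str) -> list[int]:
        return [i for i, lab in enumerate(self.channel_labels)
                if self.layer_map.get(lab) == layer]

    def trace(self, layer: str, reducer=np.mean) -> np.ndarray:
        """Single trace for a layer (mean over its channels by default)."""
        idx = self.channels_of_layer(layer)
        if not idx:
            raise KeyError(f"no channels labelled {layer!r}")
        if len(idx) == 1:
            return self.samples[idx[0]]
        return reducer(self.samples[idx], axis=0)

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_hz


@dataclass
class Hypnogram:
    """Per-10-s-epoch sleep-like state labels with retained PC coordinates."""

    labels: list[str]
    epoch_s: float = 10.0
    pc_coords: np.ndarray | None = None
    explained_variance: float | None = None

    def __post_init__(self) -> None:
        bad = set(self.labels) - {NREM, REM, EXCLUDED}
        if bad:
            raise ValueError(f"unknown state labels: {bad}")

    @property
    def n_epochs(self) -> int:
        return len(self.labels)

    def label_at(self, t_s: float) -> str:
        i = int(t_s // self.epoch_s)
        if i < 0 or i >= self.n_epochs:
            return EXCLUDED
        return self.labels[i]

    def bouts(self, state: str | None = None) -> list[tuple[str, float, float]]:
        """Contiguous same-state runs as (state, start_s, end_s)."""
        out: list[tuple[str, float, float]] = []
        i = 0
        while i < self.n_epochs:
            j = i
            while j < self.n_epochs and self.labels[j] == self.labels[i]:
                j += 1
            out.append((self.labels[i], i * self.epoch_s, j * self.epoch_s))
            i = j
        if state is not None:
            out = [b for b in out if b[0] == state]
        return out

    def state_mask(self, state: str, fs_hz: float, n_samples: int) -> np.ndarray:
        mask = np.zeros(n_samples, dtype=bool)
        for _, s0, s1 in self.bouts(state):
            mask[int(s0 * fs_hz):min(int(s1 * fs_hz), n_samples)] = True
        return mask

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "epoch_index": np.arange(self.n_epochs),
            "start_s": np.arange(self.n_epochs) * self.epoch_s,
            "label": self.labels,
        })
        if self.pc_coords is not None:
            df["pc1"] = self.pc_coords[:, 0]
            df["pc2"] = self.pc_coords[:, 1]
        else:
            df["pc1"] = np.nan
            df["pc2"] = np.nan
        return df


@dataclass(frozen=True)
class Interval:
    """Detected oscillatory span [start_s, end_s] with its peak timestamp."""

    start_s: float
    peak_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not (self.start_s <= self.peak_s <= self.end_s):
            raise ValueError("require start <= peak <= end")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


EVENTS_COLUMNS = ["event_id", "type", "start_s", "peak_s", "end_s",
                  "n_sw_overlaps", "state", "bin_index"]


def empty_events_frame() -> pd.DataFrame:
    return pd.DataFrame({
        "event_id": pd.Series(dtype=int),
        "type": pd.Series(dtype=str),
        "start_s": pd.Series(dtype=float),
        "peak_s": pd.Series(dtype=float),
        "end_s": pd.Series(dtype=float),
        "n_sw_overlaps": pd.Series(dtype=int),
        "state": pd.Series(dtype=str),
        "bin_index": pd.Series(dtype=int),
    })


# ---------------------------------------------------------------------------
# Raw binary + sidecar recording format
# ---------------------------------------------------------------------------

def write_recording(rec: LaminarRecording, out_dir: str | Path,
                    stem: str = "recording") -> Path:
    """Write little-endian float32 channel-major binary plus JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    raw = out_dir / f"{stem}.dat"
    rec.samples.astype("<f4").tofile(raw)
    sidecar = {
        "fs_hz": rec.fs_hz,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "channel_labels": list(rec.channel_labels),
        "depth_um": [float(d) for d in rec.depth_um],
        "layer_map": dict(rec.layer_map),
        "start_clock_s": rec.start_clock_s,
        "units": "uV",
        "dtype": "<f4",
        "order": "channel_major",
    }
    (out_dir / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
    return raw


def read_recording(out_dir: str | Path, stem: str = "recording") -> LaminarRecording:
    out_dir = Path(out_dir)
    meta = json.loads((out_dir / f"{stem}.json").read_text())
    raw = np.fromfile(out_dir / f"{stem}.dat", dtype=meta.get("dtype", "<f4"))
    samples = raw.reshape(meta["n_channels"], meta["n_samples"]).astype(np.float64)
    return LaminarRecording(
        samples=samples,
        fs_hz=meta["fs_hz"],
        channel_labels=meta["channel_labels"],
        depth_um=np.asarray(meta["depth_um"]),
        layer_map=meta["layer_map"],
        start_clock_s=meta.get("start_clock_s", 0.0),
    )


def write_hypnogram(hyp: Hypnogram, path: str | Path) -> None:
    hyp.to_frame().to_csv(path, sep="\t", index=False)


def read_hypnogram(path: str | Path) -> Hypnogram:
    df = pd.read_csv(path, sep="\t")
    pc = df[["pc1", "pc2"]].to_numpy() if "pc1" in df else None
    return Hypnogram(labels=list(df["label"]), pc_coords=pc)
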