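"""Sleep-like state scoring: multitaper features, PCA, 2-means.

Each 10-s epoch of one hippocampal (stratum pyramidale) and one prefrontal
trace is summarised by band powers from a multitaper spectrum (NW = 4,
0-100 Hz on a 0.5 Hz grid), the theta/slow-oscillation ratio and the epoch
amplitude.  Features from the two areas are concatenated, z-scored and
projected on the first two principal components; 2-means in that plane
separates NonREM-like from REM-like epochs, with the higher-PC1 cluster
(PC1 oriented so slow-oscillation power and amplitude load positively)
labelled NonREM-like.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import windows
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .core import EXCLUDED, NREM, REM, Hypnogram

BANDS = {
    "so": (0.1, 1.0),
    "delta": (1.0, 3.0),
    "theta": (3.0, 6.0),
    "low_beta": (10.0, 20.0),
    "low_gamma": (30.0, 45.0),
    "high_gamma": (55.0, 80.0),
    "ripple": (90.0, 300.0),
}

EPOCH_S = 10.0
_NW = 4.0
_FREQ_STEP = 0.5
_FREQ_MAX = 100.0


from functools import lru_cache


@lru_cache(maxsize=8)
def _dpss_tapers(n: int, k: int) -> np.ndarray:
    return windows.dpss(n, _NW, Kmax=k)


def _multitaper_psd(x: np.ndarray, fs_hz: float):
    """Average-of-tapered-periodograms PSD (DPSS, NW=4, 2NW-1 tapers)."""
    n = len(x)
    k = int(2 * _NW - 1)
    tapers = _dpss_tapers(n, k)
    spec = np.fft.rfft(tapers * x[None, :], axis=1)
    psd = (np.abs(spec) ** 2).mean(axis=0) / fs_hz
    freqs = np.fft.rfftfreq(n, d=1.0 / fs_hz)
    return freqs, psd


def _bin_to_grid(freqs: np.ndarray, psd: np.ndarray):
    """Aggregate the native resolution onto the 0-100 Hz, 0.5 Hz grid."""
    grid = np.arange(0.0, _FREQ_MAX + _FREQ_STEP, _FREQ_STEP)
    idx = np.clip(np.round(freqs / _FREQ_STEP).astype(int), 0, len(grid) - 1)
    keep = freqs <= _FREQ_MAX + _FREQ_STEP / 2
    binned = np.bincount(idx[keep], weights=psd[keep], minlength=len(grid))
    return grid, binned


def _band_power(grid, psd, lo, hi, full_freqs=None, full_psd=None):
    if hi > _FREQ_MAX and full_freqs is not None:
        sel = (full_freqs >= lo) & (full_freqs <= hi)
        return float(np.sum(full_psd[sel]))
    sel = (grid >= lo) & (grid <= hi)
    return float(np.sum(psd[sel]))


def compute_epoch_features(hpc: np.ndarray, pfc: np.ndarray, fs_hz: float,
                           epoch_s: float = EPOCH_S,
                           outlier_factor: float = 3.0) -> pd.DataFrame:
    """Per-epoch spectral/amplitude features for both areas.

    Epochs whose peak absolute amplitude is a scaled-MAD outlier (factor 3,
    in either area) are flagged invalid and excluded from clustering.
    """
    hpc = np.asarray(hpc, dtype=float)
    pfc = np.asarray(pfc, dtype=float)
    if hpc.shape != pfc.shape:
        raise ValueError("traces must have equal length")
    n_ep = int(len(hpc) // (epoch_s * fs_hz))
    if n_ep < 1:
        raise ValueError("need at least one full epoch")
    ns = int(epoch_s * fs_hz)
    rows = []
    for e in range(n_ep):
        row: dict = {"epoch_index": e, "start_s": e * epoch_s}
        for area, trace in (("hpc", hpc), ("pfc", pfc)):
            seg = trace[e * ns:(e + 1) * ns]
            freqs, psd = _multitaper_psd(seg, fs_hz)
            grid, binned = _bin_to_grid(freqs, psd)
            for name, (lo, hi) in BANDS.items():
                row[f"{area}_{name}"] = _band_power(grid, binned, lo, hi,
                                                    freqs, psd)
            so = row[f"{area}_so"]
            row[f"{area}_theta_so_ratio"] = (row[f"{area}_theta"] / so
                                             if so > 0 else 0.0)
            row[f"{area}_amplitude"] = float(np.max(np.abs(seg))) if ns else 0.0
        rows.append(row)
    df = pd.DataFrame(rows)

    valid = np.ones(n_ep, dtype=bool)
    for area in ("hpc", "pfc"):
        amp = df[f"{area}_amplitude"].to_numpy()
        med = np.median(amp)
        mad = stats.median_abs_deviation(amp, scale="normal")
        if mad > 0:
            valid &= np.abs(amp - med) <= outlier_factor * mad
    df["epoch_valid"] = valid
    return df


FEATURE_COLUMNS = [f"{a}_{f}" for a in ("hpc", "pfc")
                   for f in list(BANDS) + ["theta_so_ratio", "amplitude"]]


def classify_states(features: pd.DataFrame, seed: int = 0) -> Hypnogram:
    """PCA + 2-means state labels from an epoch-feature table."""
    valid = features["epoch_valid"].to_numpy()
    X = features.loc[valid, FEATURE_COLUMNS].to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two valid epochs")
    # band powers and amplitudes are heavy-tailed; log-compress before
    # z-scoring so no single high-power epoch dominates the PCs
    if np.all(X >= 0):
        X = np.log10(np.maximum(X, max(X.max(), 1e-30) * 1e-12))
    sd = X.std(axis=0)
    if np.all(sd == 0):
        raise ValueError("constant features: states cannot be separated")
    Xz = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

    pca = PCA(n_components=2, random_state=seed)
    pcs = pca.fit_transform(Xz)
    # Orient PC1 so slow-oscillation power and amplitude load positively.
    key = [FEATURE_COLUMNS.index(c) for c in
           ("hpc_so", "pfc_so", "hpc_amplitude", "pfc_amplitude")]
    if pca.components_[0, key].sum() < 0:
        pcs[:, 0] *= -1.0
    if pca.components_[1, key].sum() < 0:
        pcs[:, 1] *= -1.0
    evr = float(pca.explained_variance_ratio_.sum())

    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    assign = km.fit_predict(pcs)
    if len(set(assign)) < 2:
        warnings.warn("degenerate clustering: a single state present")
    mean_pc1 = [pcs[assign == c, 0].mean() if np.any(assign == c) else -np.inf
                for c in (0, 1)]
    nrem_cluster = int(np.argmax(mean_pc1))

    labels = []
    pc_coords = np.full((len(features), 2), np.nan)
    j = 0
    for i in range(len(features)):
        if not valid[i]:
            labels.append(EXCLUDED)
            continue
        labels.append(NREM if assign[j] == nrem_cluster else REM)
        pc_coords[i] = pcs[j]
        j += 1

    hyp = Hypnogram(labels=labels, epoch_s=EPOCH_S, pc_coords=pc_coords,
                    explained_variance=evr)
    _check_so_ordering(features, hyp)
    return hyp


def _check_so_ordering(features: pd.DataFrame, hyp: Hypnogram) -> None:
    lab = np.array(hyp.labels)
    so = features["pfc_so"].to_numpy() + features["hpc_so"].to_numpy()
    if (lab == NREM).any() and (lab == REM).any():
        if so[lab == NREM].mean() <= so[lab == REM].mean():
            warnings.warn("NonREM-like cluster does not have the higher "
                          "slow-oscillation power; check the fixture")


def score_states(hpc: np.ndarray, pfc: np.ndarray, fs_hz: float,
                 seed: int = 0) -> Hypnogram:
    """Convenience wrapper: features then classification."""
    return classify_states(compute_epoch_features(hpc, pfc, fs_hz), seed=seed)
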