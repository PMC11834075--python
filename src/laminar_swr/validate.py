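"""Ground-truth validation utilities.

Helpers to score the detection pipeline against the synthetic generator's
annotations: peak-matching recall/precision per event type, and a one-call
"simulate, preprocess, score, detect" runner used by validation scripts.
"""

from __future__ import annotations

import tempfile

import numpy as np
import pandas as pd

from .core import NREM
from .pipeline import Pipeline, PipelineConfig
from .synth import GroundTruth, SimConfig, generate_recording

PEAK_MATCH_TOL_S = 0.05


def run_detection(sim: SimConfig, out_dir: str | None = None):
    """Simulate one recording and run the pipeline through detection.

    Returns ``(events, ground_truth, pipeline_results)`` where ``events``
    is the detected NonREM-like event table.
    """
    cfg = PipelineConfig(sim=sim, seed=sim.seed)
    if out_dir is None:
        out_dir = tempfile.mkdtemp(prefix="laminar_swr_")
    p = Pipeline(cfg, out_dir)
    rec, gt = generate_recording(sim)
    pre = p.preprocess(rec)
    hyp = p.score_states(pre)
    events = p.detect(pre, hyp)
    return events[events["state"] == NREM], gt, {
        "pre": pre, "hyp": hyp, "pipeline": p, "recording": rec}


def _matched(peaks_a: np.ndarray, peaks_b: np.ndarray,
             tol_s: float) -> np.ndarray:
    if len(peaks_b) == 0:
        return np.zeros(len(peaks_a), dtype=bool)
    return np.array([np.min(np.abs(peaks_b - t)) <= tol_s for t in peaks_a])


def detection_scores(gt: GroundTruth, detected: pd.DataFrame,
                     tol_s: float = PEAK_MATCH_TOL_S) -> pd.DataFrame:
    """Per-type recall and precision with peak matching.

    A ground-truth event is recalled when a detected event of the same type
    has its peak within ``tol_s``; a detected event is a true positive when
    a same-type ground-truth peak lies within ``tol_s``.
    """
    gt_frame = gt.events_frame()
    rows = []
    for etype in ("R", "SW", "SWR", "cSWR"):
        g = gt_frame.loc[gt_frame["type"] == etype, "peak_s"].to_numpy()
        d = detected.loc[detected["type"] == etype, "peak_s"].to_numpy()
        rows.append({
            "type": etype, "n_true": len(g), "n_detected": len(d),
            "recall": float(_matched(g, d, tol_s).mean()) if len(g) else np.nan,
            "precision": float(_matched(d, g, tol_s).mean()) if len(d) else np.nan,
        })
    return pd.DataFrame(rows)


def seed_averaged_scores(base_sim: SimConfig, seeds,
                         tol_s: float = PEAK_MATCH_TOL_S) -> pd.DataFrame:
    """Mean per-type recall/precision over several generator seeds."""
    frames = []
    for s in seeds:
        sim = SimConfig(**{**base_sim.__dict__, "seed": int(s)})
        det, gt, _ = run_detection(sim)
        frames.append(detection_scores(gt, det, tol_s))
    allf = pd.concat(frames)
    return allf.groupby("type", as_index=False)[
        ["recall", "precision"]].mean()
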