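"""End-to-end orchestration: simulate -> preprocess -> score -> detect ->
features -> CSD -> spectral -> phase -> report.

Every stage reads and writes plain-text/JSON artifacts in one output
directory, records itself in a run manifest, and is deterministic given the
configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import csd as csd_mod
from . import detect as detect_mod
from . import features as feat_mod
from . import phase as phase_mod
from . import spectral as spec_mod
from .core import (NREM, Hypnogram, LaminarRecording, read_recording,
                   write_hypnogram, write_recording)
from .preprocess import (ArtifactSet, antialias_downsample, bandpass,
                         blank_artifacts, detect_artifacts, trim_and_bin)
from .states import score_states
from .synth import SimConfig, generate_recording, write_ground_truth

log = logging.getLogger("laminar_swr")

STAGES = ["simulate", "preprocess", "score_states", "detect", "features",
          "csd", "spectral", "phase", "report"]


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    target_fs_hz: float = 600.0
    discard_min: float = 0.0        # synthetic recordings have no
    # post-implantation instability; set to 15 for acquired data
    bin_min: float = 45.0
    buildup_s: float = 0.5
    washout_s: float = 3.5
    threshold_sd: float = 5.0
    min_dur_ms: float = 50.0
    merge_ms: float = 80.0
    overlap_mode: str = "literal"
    csd_capable: bool = True
    max_events_per_type_csd: int = 50
    long_short_cutoff_ms: float = 100.0
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        cfg = cls(**d)
        if isinstance(sim, dict):
            cfg.sim = SimConfig(**sim)
        return cfg

    def digest(self) -> str:
        payload = json.dumps(
            {**asdict(self), "sim": asdict(self.sim)},
            sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _manifest_update(out_dir: Path, cfg: PipelineConfig, stage: str,
                     elapsed_s: float) -> None:
    path = out_dir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {
        "config_hash": cfg.digest(), "seed": cfg.seed, "stages": {}}
    manifest["stages"][stage] = {"elapsed_s": round(elapsed_s, 3),
                                 "completed_at": time.strftime("%Y-%m-%dT%H:%M:%S")}
    path.write_text(json.dumps(manifest, indent=2))


class Pipeline:
    """Stage runner over one output directory."""

    def __init__(self, cfg: PipelineConfig, out_dir: str | Path):
        self.cfg = cfg
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)

    # -- stage: simulate ---------------------------------------------------
    def simulate(self) -> LaminarRecording:
        rec, gt = generate_recording(self.cfg.sim)
        write_recording(rec, self.out)
        write_ground_truth(gt, self.out)
        return rec

    # -- stage: preprocess -------------------------------------------------
    def preprocess(self, rec: LaminarRecording | None = None):
        cfg = self.cfg
        rec = rec or read_recording(self.out)
        if rec.fs_hz > cfg.target_fs_hz:
            rec = antialias_downsample(rec, cfg.target_fs_hz)
        sp = rec.trace("SP")
        sr = rec.trace("SR")
        pfc = rec.trace("PFC_shallow")
        artifacts = detect_artifacts(
            np.vstack([sp, pfc]), rec.fs_hz)
        # band-pass BEFORE blanking, so blanking steps never ring through
        sp_f = bandpass(sp, rec.fs_hz, *detect_mod.RIPPLE_BAND)
        sr_f = bandpass(sr, rec.fs_hz, *detect_mod.SW_BAND)
        blanked = blank_artifacts(rec, artifacts, cfg.buildup_s, cfg.washout_s)
        sp_f, sr_f = (_blank_trace(t, blanked, artifacts, cfg)
                      for t in (sp_f, sr_f))
        trimmed, bin_fn = trim_and_bin(blanked, cfg.discard_min, cfg.bin_min)
        i0 = blanked.n_samples - trimmed.n_samples
        pd.DataFrame(artifacts.intervals,
                     columns=["start_s", "end_s"]).to_csv(
            self.out / "artifacts_detected.csv", index=False)
        return {
            "recording": trimmed, "bin_fn": bin_fn,
            "sp_filtered": sp_f[i0:], "sr_filtered": sr_f[i0:],
            "artifacts": artifacts,
        }

    # -- stage: score states ----------------------------------------------
    def score_states(self, pre: dict) -> Hypnogram:
        rec = pre["recording"]
        hyp = score_states(rec.trace("SP"), rec.trace("PFC_shallow"),
                           rec.fs_hz, seed=self.cfg.seed)
        write_hypnogram(hyp, self.out / "hypnogram.tsv")
        return hyp

    # -- stage: detect -----------------------------------------------------
    def detect(self, pre: dict, hyp: Hypnogram) -> pd.DataFrame:
        cfg = self.cfg
        rec = pre["recording"]
        params = detect_mod.DetectionParams(
            threshold_sd=cfg.threshold_sd, min_dur_ms=cfg.min_dur_ms,
            merge_ms=cfg.merge_ms)
        nrem = hyp.state_mask(NREM, rec.fs_hz, rec.n_samples)
        valid = nrem & rec.valid_mask
        ripples = detect_mod.detect_ripples(pre["sp_filtered"], rec.fs_hz,
                                            params, valid=valid)
        sws = detect_mod.detect_sharp_waves(pre["sr_filtered"], rec.fs_hz,
                                            params, valid=valid)
        events = detect_mod.classify_events(ripples, sws, hyp, pre["bin_fn"],
                                            mode=cfg.overlap_mode)
        events.to_csv(self.out / "events.csv", index=False)
        return events

    # -- stage: features ---------------------------------------------------
    def features(self, pre: dict, events: pd.DataFrame) -> pd.DataFrame:
        rec = pre["recording"]
        nrem_events = events[events["state"] == NREM]
        table = feat_mod.event_feature_table(
            nrem_events, pre["sp_filtered"], pre["sr_filtered"],
            rec.trace("SR"), rec.fs_hz)
        table.to_csv(self.out / "features.csv", index=False)
        fits = {}
        for etype, grp in table.groupby("type"):
            if len(grp) >= 3:
                try:
                    fit = feat_mod.loglog_fit(grp["sr_auc_uvs"],
                                              grp["sp_auc_uvs"])
                    fits[etype] = asdict(fit)
                except ValueError:
                    continue
        (self.out / "auc_fits.json").write_text(json.dumps(fits, indent=2))
        return table

    # -- stage: csd --------------------------------------------------------
    def csd(self, pre: dict, events: pd.DataFrame):
        if not self.cfg.csd_capable:
            log.warning("csd stage skipped: probe not flagged csd-capable")
            return None
        rec = pre["recording"]
        nrem = events[events["state"] == NREM]
        subset = nrem.groupby("type", group_keys=False).head(
            self.cfg.max_events_per_type_csd)
        windows, n_skipped = csd_mod.extract_peri_event_windows(rec, subset)
        if not windows:
            return None
        table = csd_mod.layer_avrec_table(windows, rec.layer_map)
        table.to_csv(self.out / "avrec.csv", index=False)
        if (table["type"] == "SWR").any():
            delta = csd_mod.delta_avrec(table, "SWR")
            delta.to_csv(self.out / "delta_avrec.csv", index=False)
        log.info("csd: %d windows (%d skipped at edges)", len(windows),
                 n_skipped)
        return table

    # -- stage: spectral ---------------------------------------------------
    def spectral(self, pre: dict, events: pd.DataFrame) -> pd.DataFrame:
        rec = pre["recording"]
        nrem = events[events["state"] == NREM]
        subset = nrem.groupby("type", group_keys=False).head(
            self.cfg.max_events_per_type_csd)
        windows, _ = csd_mod.extract_peri_event_windows(rec, subset)
        rows = []
        for w in windows:
            prof = csd_mod.compute_csd(w)
            _, per_layer = csd_mod.compute_avrec(prof, rec.layer_map)
            if "SR" not in per_layer:
                continue
            idx = [i for i, lab in enumerate(prof.channel_labels)
                   if rec.layer_map.get(lab) == "SR"]
            trace = prof.csd[idx].mean(axis=0)
            spec = spec_mod.morlet_spectrogram(trace, rec.fs_hz)
            center = (len(trace) / 2.0) / rec.fs_hz
            fit = spec_mod.fit_spectral_slope(spec, center)
            rows.append({"type": w.event_type, "peak_s": w.peak_s,
                         "slope": fit.slope, "offset": fit.offset,
                         "r2": fit.r2})
        table = pd.DataFrame(rows, columns=["type", "peak_s", "slope",
                                            "offset", "r2"])
        table.to_csv(self.out / "spectral_slopes.csv", index=False)
        # baseline PSD of the pyramidal-layer LFP
        sp = pre["recording"].trace("SP")
        if len(sp) >= 4 * rec.fs_hz:
            freqs, logpsd, _ = spec_mod.compute_psd(sp, rec.fs_hz)
            pd.DataFrame({"freq_hz": freqs, "log10_psd": logpsd}).to_csv(
                self.out / "baseline_psd.csv", index=False)
        return table

    # -- stage: phase ------------------------------------------------------
    def phase(self, pre: dict, events: pd.DataFrame, hyp: Hypnogram):
        rec = pre["recording"]
        pfc = rec.trace("PFC_shallow")
        phase_deg, _ = phase_mod.compute_so_phase(pfc, hyp, rec.fs_hz)
        nrem = events[events["state"] == NREM]
        table, summary = phase_mod.event_phase_stats(nrem, phase_deg,
                                                     rec.fs_hz)
        table.to_csv(self.out / "phases.csv", index=False)
        summary.to_csv(self.out / "phase_summary.csv", index=False)
        deltas, counts = phase_mod.detect_delta_waves(pfc, rec.fs_hz,
                                                      bin_fn=pre["bin_fn"])
        deltas.to_csv(self.out / "delta_waves.csv", index=False)
        rates = phase_mod.bout_edge_ripple_rate(nrem, hyp)
        rates.to_csv(self.out / "bout_rates.csv", index=False)
        return summary

    # -- stage: report -----------------------------------------------------
    def report(self, events: pd.DataFrame, hyp: Hypnogram) -> dict:
        nrem = events[events["state"] == NREM]
        counts = nrem.groupby(["type", "bin_index"]).size()
        nrem_min = sum(b[2] - b[1] for b in hyp.bouts(NREM)) / 60.0
        ratio, n_long, n_short = phase_mod.long_short_ratio(
            nrem, self.cfg.long_short_cutoff_ms)
        report = {
            "counts_per_type": nrem["type"].value_counts().to_dict(),
            "counts_per_type_per_bin": {
                f"{t}/bin{b}": int(c) for (t, b), c in counts.items()},
            "nrem_like_minutes": round(nrem_min, 2),
            "rates_per_min": {
                t: round(c / nrem_min, 3) if nrem_min else None
                for t, c in nrem["type"].value_counts().items()},
            "long_short_ratio": None if np.isnan(ratio) else round(ratio, 4),
            "n_long": n_long, "n_short": n_short,
            "pc_explained_variance": hyp.explained_variance,
        }
        (self.out / "report.json").write_text(json.dumps(report, indent=2))
        return report

    # -- whole run ---------------------------------------------------------
    def run(self, simulate: bool = True) -> dict:
        t_all = time.time()
        results: dict = {}
        t0 = time.time()
        rec = self.simulate() if simulate else read_recording(self.out)
        _manifest_update(self.out, self.cfg, "simulate", time.time() - t0)
        for stage in STAGES[1:]:
            t0 = time.time()
            try:
                if stage == "preprocess":
                    results["pre"] = self.preprocess(rec)
                elif stage == "score_states":
                    results["hyp"] = self.score_states(results["pre"])
                elif stage == "detect":
                    results["events"] = self.detect(results["pre"],
                                                    results["hyp"])
                elif stage == "features":
                    results["features"] = self.features(results["pre"],
                                                        results["events"])
                elif stage == "csd":
                    results["avrec"] = self.csd(results["pre"],
                                                results["events"])
                elif stage == "spectral":
                    results["slopes"] = self.spectral(results["pre"],
                                                      results["events"])
                elif stage == "phase":
                    results["phase"] = self.phase(results["pre"],
                                                  results["events"],
                                                  results["hyp"])
                elif stage == "report":
                    results["report"] = self.report(results["events"],
                                                    results["hyp"])
            except Exception:
                log.error("pipeline aborted at stage %r", stage)
                raise
            _manifest_update(self.out, self.cfg, stage, time.time() - t0)
            log.info("stage %s done (%.1f s)", stage, time.time() - t0)
        log.info("pipeline complete (%.1f s)", time.time() - t_all)
        return results


def _blank_trace(trace: np.ndarray, blanked_rec: LaminarRecording,
                 artifacts: ArtifactSet, cfg: PipelineConfig) -> np.ndarray:
    """Apply the recording's blanking spans to an already-filtered trace."""
    out = trace.copy()
    blank = ~blanked_rec.valid_mask
    if blank.any():
        out[blank] = out[~blank].mean()
    return out


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path,
                 simulate: bool = True) -> dict:
    return Pipeline(cfg, out_dir).run(simulate=simulate)
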