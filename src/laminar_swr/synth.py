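"""Synthetic laminar LFP generator with ground truth.

Emulates urethane sleep-like recordings from a 32-channel CA1 laminar probe
plus two prefrontal channels: NonREM-like bouts carry a high-amplitude
0.5-1 Hz cortical slow oscillation, REM-like bouts carry 3-6 Hz theta, all
channels carry 1/f^beta background noise, and hippocampal events of the four
types (R, SW, SWR, cSWR) are injected at known slow-oscillation phases with
layer-specific depth profiles.  Stratum-radiatum components model CA3
(Schaffer collateral) drive and scale with ``sr_input_gain``;
lacunosum-moleculare components model entorhinal drive and scale with
``slm_input_gain`` — lowering the SR gain is the "CBD-like" manipulation.

Every draw descends from a single seed, so a fixed config is bit-identical
across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (EVENT_TYPES, NREM, REM, LaminarRecording, write_recording)

# Channel geometry: 32 hippocampal channels shallow->deep, then PFC pair.
N_HPC_CHANNELS = 32
LAYER_BLOCKS = {"SO": range(0, 6), "SP": range(6, 10),
                "SR": range(10, 22), "SLM": range(22, 32)}
# Depth-profile centres/widths in channel-index units.  Gaussian bumps give
# a CSD (second spatial difference) with one focal extremum flanked by
# opposite-sign lobes that sum to ~zero across channels.
SP_CENTER, SP_SIGMA = 7.5, 1.5
SR_CENTER, SR_SIGMA = 16.0, 2.5
SLM_CENTER, SLM_SIGMA = 26.5, 2.0

_DEFAULT_RATES = {"R": 2.0, "SW": 2.0, "SWR": 3.0, "cSWR": 1.0}
_DEFAULT_PHASES = {"R": 0.0, "SW": 270.0, "SWR": 270.0, "cSWR": 270.0}


class GenerationError(RuntimeError):
    pass


@dataclass
class SimConfig:
    """Study conditions for one synthetic recording."""

    duration_s: float = 1800.0
    fs_hz: float = 600.0
    n_channels: int = N_HPC_CHANNELS + 2
    channel_spacing_um: float = 50.0
    noise_beta: float = 2.0
    noise_rms_uv: float = 350.0
    noise_spatial_sigma_ch: float = 5.0
    event_rates: dict = field(default_factory=lambda: dict(_DEFAULT_RATES))
    sr_input_gain: float = 1.0
    slm_input_gain: float = 1.0
    state_bout_s: tuple = (240.0, 90.0)  # mean NonREM-like / REM-like bout
    event_phase_deg: dict = field(default_factory=lambda: dict(_DEFAULT_PHASES))
    so_amp_uv: float = 300.0
    so_freq_range_hz: tuple = (0.5, 1.0)
    theta_amp_uv: float = 40.0
    theta_freq_range_hz: tuple = (3.0, 6.0)
    rem_noise_gain: float = 0.5
    artifact_rate_per_hr: float = 2.0
    allow_rem_placement: bool = False
    ripple_duration_sr_coupling: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fs_hz <= 2 * 200.0:
            raise ValueError("fs_hz must exceed twice the highest injected frequency")
        if self.sr_input_gain < 0 or self.slm_input_gain < 0:
            raise ValueError("gains must be >= 0")
        if any(r < 0 for r in self.event_rates.values()):
            raise ValueError("event rates must be >= 0")


@dataclass
class GroundTruth:
    """What was injected: events, state schedule, artifact times."""

    events: list  # (type, start_s, peak_s, end_s, n_sw_components)
    state_schedule: list  # (state, start_s, end_s)
    artifact_times: list

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=[
            "type", "start_s", "peak_s", "end_s", "n_sw_components"])

    def schedule_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.state_schedule,
                            columns=["state", "start_s", "end_s"])


# ---------------------------------------------------------------------------
# Background noise
# ---------------------------------------------------------------------------

def generate_noise(n_samples: int, fs_hz: float, beta: float,
                   rms_uv: float, seed: int) -> np.ndarray:
    """1/f^beta noise by frequency-domain shaping of a white spectrum.

    The amplitude spectrum is shaped as f^(-beta/2) so the expected
    periodogram follows f^(-beta) exactly; the trace is rescaled to the
    requested RMS.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if rms_uv < 0:
        raise ValueError("rms_uv must be >= 0")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if rms_uv == 0:
        return np.zeros(n_samples)
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs_hz)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-beta / 2.0)
    re = rng.standard_normal(len(freqs))
    im = rng.standard_normal(len(freqs))
    spec = (re + 1j * im) * shape
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n_samples)
    x *= rms_uv / np.sqrt(np.mean(x ** 2))
    return x


# ---------------------------------------------------------------------------
# Depth profiles and event templates
# ---------------------------------------------------------------------------

def _gauss_profile(center: float, sigma: float) -> np.ndarray:
    z = np.arange(N_HPC_CHANNELS, dtype=float)
    return np.exp(-0.5 * ((z - center) / sigma) ** 2)


def _dipole_profile(center: float, sigma: float) -> np.ndarray:
    z = np.arange(N_HPC_CHANNELS, dtype=float)
    u = (z - center) / sigma
    p = -u * np.exp(-0.5 * u ** 2)
    return p / np.max(np.abs(p))


@dataclass
class TemplateParams:
    """Phenomenological event-template settings (amplitudes in uV, times s).

    Ripple durations are the FWHM of the Gaussian envelope; the snippet
    support extends to 2.5 envelope sigmas either side of the peak.
    """

    ripple_freq_hz: float = 150.0
    r_dur_s: tuple = (0.06, 0.10)
    cswr_dur_s: tuple = (0.15, 0.30)
    sw_dur_s: tuple = (0.04, 0.08)
    ripple_amp_uv: float = 25.0
    ripple_amp_logsd: float = 0.2
    sw_amp_uv: float = 260.0
    sw_amp_logsd: float = 0.35
    slm_amp_uv: float = 40.0
    slm_dur_s: float = 0.12


_ENV_SUPPORT_SIGMAS = 2.5
_FWHM_SIGMAS = 2.0 * math.sqrt(2.0 * math.log(2.0))


def _ripple_component(fs_hz: float, fwhm_s: float, amp: float, freq: float):
    sigma = fwhm_s / _FWHM_SIGMAS
    half = _ENV_SUPPORT_SIGMAS * sigma
    n = 2 * int(round(half * fs_hz)) + 1
    t = (np.arange(n) - n // 2) / fs_hz
    env = np.exp(-0.5 * (t / sigma) ** 2)
    return amp * env * np.cos(2 * np.pi * freq * t), n // 2


def _sw_component(fs_hz: float, dur_s: float, amp: float) -> np.ndarray:
    n = max(int(round(dur_s * fs_hz)), 3)
    t = np.arange(n) / (n - 1)
    return -amp * np.sin(np.pi * t)


def generate_event_templates(type: str, fs_hz: float,
                             sr_input_gain: float = 1.0,
                             slm_input_gain: float = 1.0,
                             params: TemplateParams | None = None,
                             rng: np.random.Generator | None = None):
    """Build one laminar event snippet plus component annotations.

    Returns ``(snippet, components)`` where ``snippet`` is a 32 x n matrix
    over the hippocampal channels and ``components`` is a list of dicts with
    keys ``kind`` ('ripple'|'sw'|'slm'), ``peak_s``, ``start_s``, ``end_s``
    (relative to the snippet start) and ``amp_uv``.  The snippet peak
    (ripple envelope maximum, or SW trough for a standalone SW) is at the
    snippet centre.
    """
    if type not in EVENT_TYPES:
        raise ValueError(f"unknown event type {type!r}")
    p = params or TemplateParams()
    rng = rng or np.random.default_rng(0)

    ripple_fwhm = None
    sw_offsets: list[float] = []
    if type == "R" or type == "SWR":
        ripple_fwhm = rng.uniform(*p.r_dur_s)
    elif type == "cSWR":
        ripple_fwhm = rng.uniform(*p.cswr_dur_s)
    if type == "SWR":
        sw_offsets = [0.0]
    elif type == "SW":
        sw_offsets = [0.0]
    elif type == "cSWR":
        n_sw = 3 if ripple_fwhm > 0.24 else 2
        spread = 0.120  # trough spacing, keeps SW components disjoint
        # after band-pass filtering
        sw_offsets = [spread * (k - (n_sw - 1) / 2.0) for k in range(n_sw)]

    sw_durs = [rng.uniform(*p.sw_dur_s) for _ in sw_offsets]
    ripple_amp = p.ripple_amp_uv * rng.lognormal(0.0, p.ripple_amp_logsd)
    sw_amps = [p.sw_amp_uv * rng.lognormal(0.0, p.sw_amp_logsd)
               for _ in sw_offsets]

    # Snippet support: widest component either side of the anchor.
    half = 0.0
    if ripple_fwhm is not None:
        half = max(half, _ENV_SUPPORT_SIGMAS * ripple_fwhm / _FWHM_SIGMAS)
        half = max(half, p.slm_dur_s / 2.0 + 0.01)
    for off, d in zip(sw_offsets, sw_durs):
        half = max(half, abs(off) + d / 2.0 + 0.01)
    n = 2 * int(round(half * fs_hz)) + 1
    center = n // 2
    snippet = np.zeros((N_HPC_CHANNELS, n))
    components = []

    if ripple_fwhm is not None:
        burst, bc = _ripple_component(fs_hz, ripple_fwhm, ripple_amp,
                                      p.ripple_freq_hz)
        i0 = center - bc
        snippet[:, i0:i0 + len(burst)] += np.outer(
            _gauss_profile(SP_CENTER, SP_SIGMA), burst)
        components.append(dict(
            kind="ripple", peak_s=center / fs_hz,
            start_s=(center / fs_hz) - ripple_fwhm / 2.0,
            end_s=(center / fs_hz) + ripple_fwhm / 2.0, amp_uv=ripple_amp))
        # Entorhinal-like dipolar deflection in SLM under the ripple.
        slm_amp = p.slm_amp_uv * slm_input_gain
        if slm_amp > 0:
            ns = int(round(p.slm_dur_s * fs_hz)) | 1
            ts = (np.arange(ns) - ns // 2) / fs_hz
            g = np.exp(-0.5 * (ts / (p.slm_dur_s / 4.0)) ** 2)
            j0 = center - ns // 2
            snippet[:, j0:j0 + ns] += np.outer(
                slm_amp * _dipole_profile(SLM_CENTER, SLM_SIGMA), g)
            components.append(dict(
                kind="slm", peak_s=center / fs_hz,
                start_s=(center - ns // 2) / fs_hz,
                end_s=(center + ns // 2) / fs_hz, amp_uv=slm_amp))

    for off, d, a in zip(sw_offsets, sw_durs, sw_amps):
        wave = _sw_component(fs_hz, d, a * sr_input_gain)
        t_trough = center / fs_hz + off
        i0 = int(round((t_trough - d / 2.0) * fs_hz))
        seg = wave[:min(len(wave), n - i0)]
        snippet[:, i0:i0 + len(seg)] += np.outer(
            _gauss_profile(SR_CENTER, SR_SIGMA), seg)
        components.append(dict(
            kind="sw", peak_s=t_trough, start_s=t_trough - d / 2.0,
            end_s=t_trough + d / 2.0, amp_uv=a * sr_input_gain))

    return snippet, components


# ---------------------------------------------------------------------------
# State schedule, oscillatory background, event placement
# ---------------------------------------------------------------------------

def _make_schedule(duration_s: float, bout_means: tuple,
                   rng: np.random.Generator) -> list:
    """Alternating NonREM-like / REM-like bouts.

    Durations are uniform in 0.6-1.4 x the state's mean (urethane state
    alternation is fairly regular), and bout boundaries snap to the 10-s
    scoring-epoch grid so a ground-truth bout never splits an epoch.
    """
    sched = []
    t, state = 0.0, NREM
    min_bout = 30.0
    while t < duration_s:
        mean = bout_means[0] if state == NREM else bout_means[1]
        dur = max(min_bout,
                  10.0 * round(mean * rng.uniform(0.6, 1.4) / 10.0))
        end = min(t + dur, duration_s)
        sched.append((state, t, end))
        t = end
        state = REM if state == NREM else NREM
    return sched


def _blank_window(t: float) -> tuple:
    # artifact blanking span (0.5 s buildup, 3.5 s washout) plus margin
    return (t - 1.0, t + 4.5)


def generate_recording(config: SimConfig):
    """Generate one recording plus its complete ground truth.

    Deterministic given ``config.seed``: all randomness descends from one
    SeedSequence, with event placement independent of the input gains so
    that two configs differing only in gain share event times.
    """
    fs = config.fs_hz
    n = int(round(config.duration_s * fs))
    ss = np.random.SeedSequence(config.seed)
    s_sched, s_noise, s_osc, s_events, s_artifacts = ss.spawn(5)
    rng_sched = np.random.default_rng(s_sched)
    rng_osc = np.random.default_rng(s_osc)
    rng_events = np.random.default_rng(s_events)
    rng_art = np.random.default_rng(s_artifacts)

    schedule = _make_schedule(config.duration_s, config.state_bout_s, rng_sched)
    nrem_bouts = [b for b in schedule if b[0] == NREM]
    # occupancy check: injected events must fit inside NonREM-like time
    occupancy = sum(config.event_rates.values()) / 60.0 * 0.6
    if occupancy > 0.5:
        raise GenerationError(
            "total event duration would exceed the NonREM-like time "
            "available; lower the event rates")

    # --- background noise, larger during NonREM-like (slow-wave) activity
    n_ch = config.n_channels
    noise_seeds = s_noise.generate_state(n_ch)
    samples = np.empty((n_ch, n))
    for c in range(n_ch):
        samples[c] = generate_noise(n, fs, config.noise_beta,
                                    config.noise_rms_uv,
                                    int(noise_seeds[c] % (2 ** 31)))
    # Volume conduction makes neighbouring-channel noise highly correlated:
    # smooth the hippocampal noise across depth (Gaussian kernel), then
    # restore the per-channel RMS.  Correlated noise is also what keeps the
    # second spatial derivative (CSD) from amplifying channel noise.
    sig = config.noise_spatial_sigma_ch
    if sig > 0:
        off = np.arange(-int(np.ceil(3 * sig)), int(np.ceil(3 * sig)) + 1)
        kern = np.exp(-0.5 * (off / sig) ** 2)
        kern /= kern.sum()
        hpc = samples[:N_HPC_CHANNELS]
        sm = np.zeros_like(hpc)
        for k, o in zip(kern, off):
            src = np.clip(np.arange(N_HPC_CHANNELS) + o, 0,
                          N_HPC_CHANNELS - 1)
            sm += k * hpc[src]
        sm *= config.noise_rms_uv / np.sqrt(np.mean(sm ** 2, axis=1,
                                                    keepdims=True))
        samples[:N_HPC_CHANNELS] = sm
    gain = np.full(n, config.rem_noise_gain)
    for _, s0, s1 in nrem_bouts:
        gain[int(s0 * fs):int(s1 * fs)] = 1.0
    # soften state transitions with a 2-s moving-average ramp
    w = max(int(2.0 * fs), 1)
    c = np.cumsum(np.pad(gain, (w // 2 + 1, w // 2), mode="edge"))
    gain = (c[w:] - c[:-w])[:n] / w
    samples *= gain[None, :]

    # --- artifacts (uniform in time, all channels)
    n_art = rng_art.poisson(config.artifact_rate_per_hr *
                            config.duration_s / 3600.0)
    artifact_times = sorted(
        rng_art.uniform(20.0, config.duration_s - 20.0, size=n_art).tolist())
    t_axis = np.arange(n) / fs

    # --- slow oscillation (PFC, NonREM-like) and theta (REM-like); the SO
    # frequency is fixed within a bout so its analytic phase is known exactly.
    pfc_idx = [n_ch - 2, n_ch - 1]
    so_freq_by_bout = {}
    for bi, (state, s0, s1) in enumerate(schedule):
        i0, i1 = int(s0 * fs), int(s1 * fs)
        seg_t = t_axis[i0:i1] - s0
        ramp = np.minimum(1.0, np.minimum(seg_t, (s1 - s0) - seg_t) / 2.0)
        ramp = np.clip(ramp, 0.0, 1.0)
        if state == NREM:
            f = rng_osc.uniform(*config.so_freq_range_hz)
            so_freq_by_bout[bi] = f
            so = config.so_amp_uv * np.cos(2 * np.pi * f * seg_t) * ramp
            samples[pfc_idx[0], i0:i1] += so
            samples[pfc_idx[1], i0:i1] += 0.8 * so
        else:
            f = rng_osc.uniform(*config.theta_freq_range_hz)
            theta = np.sin(2 * np.pi * f * seg_t) * ramp
            hpc_profile = 0.6 + 0.4 * np.linspace(0, 1, N_HPC_CHANNELS)
            samples[:N_HPC_CHANNELS, i0:i1] += np.outer(
                config.theta_amp_uv * hpc_profile, theta)
            samples[pfc_idx[0], i0:i1] += 0.4 * config.theta_amp_uv * theta
            samples[pfc_idx[1], i0:i1] += 0.4 * config.theta_amp_uv * theta

    # --- event placement on slow-oscillation cycles
    tparams = TemplateParams()
    if config.ripple_duration_sr_coupling:
        scale = 0.5 + 0.5 * config.sr_input_gain
        tparams.r_dur_s = tuple(d * scale for d in tparams.r_dur_s)
        tparams.cswr_dur_s = tuple(d * scale for d in tparams.cswr_dur_s)

    blocked = [_blank_window(a) for a in artifact_times]
    events = []

    placement_bouts = [(bi, b) for bi, b in enumerate(schedule)
                       if b[0] == NREM or config.allow_rem_placement]
    for bi, (state, s0, s1) in placement_bouts:
        dur_min = (s1 - s0) / 60.0
        margin = 12.0  # clear of bout edges by more than one scoring epoch
        if state == NREM:
            f = so_freq_by_bout[bi]
            n_cycles = int((s1 - s0 - 2 * margin) * f)
            if n_cycles <= 0:
                continue
        counts = {et: rng_events.poisson(config.event_rates.get(et, 0.0) * dur_min)
                  for et in EVENT_TYPES}
        total = sum(counts.values())
        if total == 0:
            continue
        if state == NREM:
            while total > n_cycles:  # short bout: drop excess placements
                et = max(counts, key=counts.get)
                counts[et] -= 1
                total -= 1
            cycles = rng_events.choice(n_cycles, size=total, replace=False)
        else:
            cycles = None
        k = 0
        for et in EVENT_TYPES:
            for _ in range(counts[et]):
                if state == NREM:
                    # anchor exactly at the requested slow-oscillation phase:
                    # the SO is cos(2 pi f (t - s0)), so phase phi falls at
                    # t = s0 + (k + phi/360)/f for whole cycles k
                    phase = config.event_phase_deg.get(et, 0.0)
                    k0 = math.ceil(margin * f)
                    anchor = s0 + (k0 + cycles[k] + phase / 360.0) / f
                else:
                    anchor = rng_events.uniform(s0 + margin, s1 - margin)
                k += 1
                if anchor >= s1 - margin:
                    continue
                if any(b0 <= anchor <= b1 for b0, b1 in blocked):
                    continue
                snippet, comps = generate_event_templates(
                    et, fs, config.sr_input_gain, config.slm_input_gain,
                    tparams, rng_events)
                half = (snippet.shape[1] // 2) / fs
                if any(b0 <= anchor + d <= b1 for b0, b1 in blocked
                       for d in (-half, half)):
                    continue
                i0 = int(round((anchor - half) * fs))
                if i0 < 0 or i0 + snippet.shape[1] > n:
                    continue
                samples[:N_HPC_CHANNELS, i0:i0 + snippet.shape[1]] += snippet
                t0 = i0 / fs
                starts = [t0 + c["start_s"] for c in comps]
                ends = [t0 + c["end_s"] for c in comps]
                n_sw = sum(1 for c in comps if c["kind"] == "sw")
                events.append((et, min(starts), anchor, max(ends), n_sw))

    events.sort(key=lambda e: e[1])

    # --- artifact transients added last (never overlapping events)
    for a in artifact_times:
        i0 = int(a * fs)
        samples[:, i0:i0 + int(0.010 * fs)] += 3000.0

    labels = [f"hpc{c:02d}" for c in range(N_HPC_CHANNELS)] + \
             ["pfc_shallow", "pfc_deep"]
    layer_map = {}
    for layer, block in LAYER_BLOCKS.items():
        for c in block:
            layer_map[f"hpc{c:02d}"] = layer
    layer_map["pfc_shallow"] = "PFC_shallow"
    layer_map["pfc_deep"] = "PFC_deep"
    depth = np.arange(n_ch) * config.channel_spacing_um

    rec = LaminarRecording(samples=samples, fs_hz=fs, channel_labels=labels,
                           depth_um=depth, layer_map=layer_map)
    gt = GroundTruth(events=events, state_schedule=schedule,
                     artifact_times=artifact_times)
    return rec, gt


# ---------------------------------------------------------------------------
# On-disk ground truth
# ---------------------------------------------------------------------------

def write_ground_truth(gt: GroundTruth, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gt.events_frame().to_csv(out_dir / "ground_truth_events.csv", index=False)
    gt.schedule_frame().to_csv(out_dir / "state_schedule.tsv", sep="\t",
                               index=False)
    pd.DataFrame({"artifact_s": gt.artifact_times}).to_csv(
        out_dir / "artifacts.csv", index=False)


def read_ground_truth(out_dir: str | Path) -> GroundTruth:
    out_dir = Path(out_dir)
    ev = pd.read_csv(out_dir / "ground_truth_events.csv")
    sched = pd.read_csv(out_dir / "state_schedule.tsv", sep="\t")
    art = pd.read_csv(out_dir / "artifacts.csv")
    return GroundTruth(
        events=[tuple(r) for r in ev.itertuples(index=False)],
        state_schedule=[tuple(r) for r in sched.itertuples(index=False)],
        artifact_times=list(art["artifact_s"]))


def simulate_to_dir(config: SimConfig, out_dir: str | Path) -> None:
    rec, gt = generate_recording(config)
    write_recording(rec, out_dir)
    write_ground_truth(gt, out_dir)
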