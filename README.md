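# laminar-swr

Detection, classification and laminar characterisation of hippocampal
sharp-wave ripples in multi-channel LFP recordings, with a synthetic
laminar-LFP generator that makes every stage testable against ground truth.

## Who this is for

Electrophysiologists analysing laminar probe recordings from CA1 (urethane
sleep-like preparations or natural sleep) who need a reproducible, scripted
version of the classic ripple/sharp-wave workflow: sleep-like state scoring,
independent event detection in two layers, co-occurrence classification,
per-event feature tables, current-source-density (CSD) and AVREC laminar
profiles, aperiodic (1/f) spectral slopes, and slow-oscillation phase
coupling.

## The analysis

Ripples and sharp waves are detected **independently** in two CA1 layers:

* **Ripples** on the 90–200 Hz band-passed stratum-pyramidale trace: the
  Hilbert envelope must exceed mean + 5 SD for ≥ 50 ms; event edges extend
  to the half-threshold crossings; events closer than 80 ms merge.
* **Sharp waves** on the 2–20 Hz band-passed stratum-radiatum trace:
  voltage troughs below mean − 5 SD, edges at the crossings, peak at the
  minimum.

Co-occurrence is classified per ripple by counting sharp-wave overlaps via
two non-mutually-exclusive endpoint-containment cases (the sharp wave's end
or start inside the ripple's `[start, end]`): 0 overlaps → **R**, 1 →
**SWR**, ≥ 2 → **cSWR**; sharp waves belonging to no ripple → **SW**.

Downstream characterisation includes, per event:

* **AUC** — trapezoidal integral of the absolute filtered trace,
  `AUC = ∫ₐᵇ |f(x)| dx`, deliberately not amplitude-normalised so it
  reflects amplitude and duration together. The stratum-radiatum vs
  stratum-pyramidale AUC relation is summarised by a least-squares line in
  log₁₀–log₁₀ space and compared between conditions with a Fisher-z test,
  `z = (atanh r_A − atanh r_B) / √(1/(n_A−3) + 1/(n_B−3))`.
* **CSD** — second spatial difference across channels,
  `CSD_i = Θ_{i−1} − 2Θ_i + Θ_{i+1}`, and **AVREC** — the mean of |CSD|
  over channels — plus delta-AVREC relative to SWR events per layer.
* **Aperiodic slope/offset** — a line fit to log₁₀ power vs log₁₀
  frequency of a six-cycle Morlet spectrogram (1–200 Hz) in a ±250 ms
  window around the event peak; a flatter slope is conventionally read as
  a shift of the excitation/inhibition balance toward excitation.
* **Slow-oscillation phase** — the analytic-signal angle of the 0.5–4 Hz
  prefrontal trace over concatenated NonREM-like bouts (cosine convention:
  peak = 0°, trough = 180°), sampled at each event peak.

States are scored per 10-s epoch from multitaper band powers (NW = 4,
0–100 Hz), theta/slow-oscillation ratio and epoch amplitude of one
hippocampal and one prefrontal channel: PCA on log-z-scored features,
2-means in the (PC1, PC2) plane, higher-PC1 cluster = NonREM-like.

The synthetic generator (`laminar_swr.synth`) emulates the recording these
methods target: 32 laminar channels + 2 prefrontal channels at 600 Hz,
1/f² spatially-correlated background, slow oscillations in NonREM-like
bouts, theta in REM-like bouts, and the four event types injected with
known times, laminar depth profiles and slow-oscillation phases.
Stratum-radiatum event components scale with `sr_input_gain` (CA3/Schaffer
drive; < 1 models a pharmacologically reduced drive) and
lacunosum-moleculare components with `slm_input_gain` (entorhinal drive).

## Worked example

```sh
laminar-swr run --out demo --seed 11
```

simulates a 30-min recording, runs every stage and prints the report:

```json
{
  "counts_per_type": {"SW": 51, "SWR": 48, "R": 32, "cSWR": 23},
  "nrem_like_minutes": 21.5,
  "rates_per_min": {"SW": 2.372, "SWR": 2.233, "R": 1.488, "cSWR": 1.07},
  "long_short_ratio": 5.8667,
  "n_long": 88, "n_short": 15,
  "pc_explained_variance": 0.8612020903801084
}
```

21.5 of the 30 minutes were scored NonREM-like; within them the detector
found 48 sharp-wave ripples, 23 complex events (one long ripple over ≥ 2
sharp waves), 32 lone ripples and 51 lone sharp waves — per-minute rates in
the right-hand block. `long_short_ratio` is the count of ripple-bearing
events longer than 100 ms over those shorter. The first two principal
components carried 86% of the epoch-feature variance. `demo/` also holds
`events.csv`, `features.csv`, `hypnogram.tsv`, `avrec.csv`,
`delta_avrec.csv`, `spectral_slopes.csv` and `phase_summary.csv`; the
latter shows the recovered phase preferences (lone ripples at the slow
oscillation's upstate peak, sharp-wave events at the down-to-upstate
transition):

```
type,n,circ_mean_deg,resultant_length
R,32,0.679,0.999
SW,51,269.639,0.999
SWR,48,269.506,0.999
cSWR,23,268.791,0.998
```

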