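# Methods

This note records the models, conventions and numerical choices behind
`laminar_swr`, and what the synthetic fixtures do and do not establish
about real recordings.

## Signal model of the synthetic recordings

The generator emulates a urethane sleep-like preparation recorded with a
32-channel single-shank laminar probe in CA1 (50 µm spacing; the probe
geometry is an assumption — a standard single-shank layout) plus two
prefrontal channels, sampled at 600 Hz, all amplitudes in µV.

**Background.** Each channel carries 1/f^β noise (default β = 2,
350 µV RMS) synthesised by frequency-domain shaping — the amplitude
spectrum of complex white noise is multiplied by f^(−β/2), giving exact
slope control for slope-recovery tests. Hippocampal channel noise is
smoothed across depth with a Gaussian kernel (σ = 5 channels) and
re-normalised per channel: volume conduction makes neighbouring-channel
LFP noise highly correlated in vivo, and without this correlation the
second spatial derivative (CSD) would amplify channel noise to the point
of burying the event-locked laminar profile. Background amplitude is
halved in REM-like bouts (low-voltage fast activity), the main amplitude
cue the state scorer relies on in real urethane data.

**States.** NonREM-like and REM-like bouts alternate with uniform
0.6–1.4 × mean durations (defaults 240 s / 90 s), snapped to the 10-s
scoring-epoch grid. Exponential bout draws occasionally produce recordings
with almost no REM-like time, which makes any two-cluster scorer
degenerate; the study conditions require both states present. NonREM-like
bouts put a 300 µV slow oscillation (0.5–1 Hz, frequency fixed within a
bout so its analytic phase is exact) on the prefrontal channels; REM-like
bouts put 3–6 Hz, 40 µV theta on the hippocampal channels with a smooth
depth gradient. Theta is kept below the sharp-wave detection threshold so
a single mislabeled epoch cannot flood the sharp-wave pool with theta
troughs.

**Events.** Templates are phenomenological, not biophysical. Laminar
spread uses Gaussian depth profiles (pyramidale centre channel 7.5,
σ 1.5; radiatum 16, σ 2.5) whose second spatial difference yields one
focal extremum with opposite-sign flanks summing to ~zero — interpretable
CSD fixtures by construction. Ripples are Gaussian-windowed 150 Hz bursts;
the duration parameter is the envelope FWHM (R/SWR default 60–100 ms,
cSWR 150–300 ms) so that the supra-threshold core of a default-amplitude
burst comfortably clears the 50-ms duration criterion. Sharp waves are
negative half-sine deflections (40–80 ms) on the radiatum profile with
lognormal trough amplitudes (median 260 µV at the profile peak,
σ_log = 0.35); the amplitude spread is what makes a reduced
stratum-radiatum gain push a realistic fraction of components below the
fixed detection threshold. Complex events carry one long burst over 2–3
sharp waves spaced 120 ms apart — far enough that the 2–20 Hz filtered
trough spans stay separate. Ripple-bearing events add a 40 µV dipolar
(derivative-of-Gaussian) deflection on the lacunosum-moleculare profile,
scaled by `slm_input_gain`, standing in for entorhinal input.

Events are placed only in NonREM-like bouts (≥ 12 s from bout edges, i.e.
clear of the epoch that straddles a transition), one per slow-oscillation
cycle at a configurable phase — ascending zero crossing (270°, the
down-to-upstate transition) for SW/SWR/cSWR and upstate peak (0°) for R —
and never inside artifact blanking windows. All draws descend from one
`SeedSequence`, and event times/counts are independent of the input gains,
so two configs differing only in a gain are sample-aligned.

**What the fixtures do not show.** Passing tests demonstrate that the
pipeline recovers what was injected under these idealised conditions —
stationary background, template-shaped events, noiseless phase structure.
They do not establish detector performance under electrode drift,
movement artifacts, non-template event morphology, or per-animal threshold
idiosyncrasies; on real data thresholds were historically verified
visually, which the pipeline replaces with explicit config overrides.

## Preprocessing

30 kHz recordings are low-passed with a 3rd-order Butterworth at 300 Hz,
forward–backward (zero phase; the effective magnitude response is |H|²),
then integer-decimated to 600 Hz. Artifacts are flagged where the summed
absolute raw signal of selected channels crosses a threshold (default
mean + 8 SD — a reproducible stand-in for per-animal visual settings) and
blanked with a 0.5 s buildup and 3.5 s washout, replaced per channel by
the clean-sample mean. A 3.33 s washout used by one downstream variant of
the same workflow is available as `PSD_WASHOUT_S`. Band-pass filtering
for detection happens **before** blanking so the blanking steps cannot
ring through the filters; the pipeline enforces that order. The first
15 min are discarded for acquired data (instability after probe
placement); simulated recordings default to 0 since the generator has no
such transient. Analysis time is divided into 45-min bins; multi-animal
alignment by time-of-day pads with explicitly masked samples, never
numeric sentinels.

## State scoring

Per 10-s epoch and per area (hippocampal pyramidale, prefrontal):
multitaper band powers (DPSS, NW = 4, 7 tapers, 0–100 Hz summed onto a
0.5 Hz grid) for slow-oscillation (0.1–1 Hz), delta (1–3), theta (3–6),
low-beta (10–20), low-gamma (30–45), high-gamma (55–80) and ripple
(90–300) bands, the theta/SO ratio, and the epoch amplitude (max |x|).
Epochs whose amplitude is a scaled-MAD outlier (factor 3) are excluded.
Features from the two areas are concatenated (the alternative — averaging
areas — is less informative and was rejected). Band power is the discrete
sum of in-band PSD bins.

Features are log₁₀-compressed before z-scoring and PCA: band powers are
heavy-tailed (χ²-like with few degrees of freedom in the low bands), and
without compression single high-power epochs dominate the principal
components and 2-means splits the NonREM-like cluster instead of the
states. Log power is the conventional choice in sleep scoring. PC1's sign
is oriented so slow-oscillation power and amplitude load positively,
replacing manual cluster inspection; 2-means (10 restarts, fixed seed)
runs in the (PC1, PC2) plane and the higher-PC1 cluster is labelled
NonREM-like. On the synthetic fixtures PC1+PC2 carry 0.82–0.88 of the
variance and epoch agreement with the generator schedule is ≥ 0.95.

## Event detection

A 90–200 Hz oscillation cannot itself stay above a voltage threshold for
50 ms, so the ripple detection magnitude is the Hilbert envelope of the
filtered trace (a 10-ms RMS alternative is available). The threshold
baseline (mean, SD) is computed over artifact-free NonREM-like samples
only — thresholds belong to the sleep-like regime. Band-pass filters are
4th-order Butterworth, forward–backward. The 50-ms minimum applies to the
supra-threshold core, before edges are extended to half-threshold
crossings. Overlap endpoint containment is closed (ties count). The
default overlap rule is the literal two-case endpoint rule, under which a
sharp wave strictly containing a ripple counts as *no* overlap; an opt-in
`mode="intersection"` treats any interval intersection as overlap. Both
behaviours are unit-tested against a brute-force oracle.

## Event features

Feature windows: for SWR/cSWR the ripple's `[start, end]` (capturing all
sharp waves under a complex event); standalone R and SW use their own
window, with the other layer measured over the same span. Mean frequency
is the first spectral moment of the one-sided periodogram. The
sharp-wave frequency uses a 6-s Morlet spectrogram context around the
event peak (reflect-padded at trace edges); median-amplitude event
selection ranks ripple-bearing types on the pyramidale amplitude and
standalone sharp waves on the radiatum amplitude. Zero or negative AUC
values are dropped from log-log fits with the count reported. KDE contour
levels partition the density into equal mass fractions (Scott's-rule
bandwidth); the level list is ascending, innermost last.

## CSD and AVREC

CSD is the unit-spacing second spatial difference over interior channels
(boundary channels dropped; Vaknin-style edge duplication behind a flag) —
assumption-free given that only the second-derivative definition is
specified. Physical units (division by spacing²) are a caller-side
scaling since CSD is reported in arbitrary units. AVREC is the channel
mean of |CSD|; the scalar per-event summary averages the AVREC trace over
the ±0.5 s peri-event core of the 6-s window, where the event-locked
currents live (averaging the full window dilutes the event ~10× against
the stationary background). Delta-AVREC is reported in both orientations
(type − SWR and SWR − type) and in an SWR-normalised variant, with the
reference rows identically zero.

Under the second-difference sign convention used here, a focal *negative*
potential deflection produces a *positive* central second difference
flanked by negatives; the rectified AVREC and all direction tests are
insensitive to this sign choice.

## Wavelets and aperiodic slope

One Morlet definition serves the whole package: fixed six cycles
(σ_t = n_cycles/(2πf)), wavelets L1-normalised on their envelope with the
analytic factor 2, so a tone of amplitude A yields peak power A² at every
analysis frequency (1–200 Hz, 1 Hz grid). For quantitative uses the power
is converted to a spectral density by dividing by the per-frequency
equivalent noise bandwidth (ENBW = 1/(√π σ_t), which grows linearly with
frequency for fixed cycles): without this, broadband 1/f^β noise appears
one power of f shallower than it is, and multi-component weighted-mean
frequencies are biased high. The slope fit floors non-positive power at
10⁻¹² of the maximum (count reported) and regresses log₁₀ density on
log₁₀ frequency by least squares, by default over a ±250 ms window around
the event peak; the pipeline feeds the radiatum-layer CSD average per
event (the CSD is more local than the LFP, which is the reason slope
analysis is run on it), raw LFP for baseline PSDs. Welch PSDs use 4-s
Hann segments with 0.25-s overlap (0.25 Hz grid, 0–100 Hz) and a
pre-PSD 50 Hz notch (2nd-order IIR, Q = 30).

## Phase, delta waves, rates

Slow-oscillation phase: 3rd-order Butterworth 0.5–4 Hz on the prefrontal
trace, Hilbert transform of the *concatenated* NonREM-like signal, angle
mapped to [0°, 360°) with the cosine convention (peak = 0°,
trough = 180°, ascending zero crossing = 270°), then split back per bout.
The absolute 0° reference of a recorded downstate depends on electrode
polarity, so real-data phase preferences are meaningful only up to a
constant offset; the synthetic tests therefore validate recovery of
*injected* phases rather than absolute positions. Cortical delta waves
are biphasic 1–6 Hz deflections (zero-crossing delimited, positive peak
then trough, thresholds defaulting to +2 SD / −1.5 SD, duration
150–550 ms). Bout-edge ripple rates use NonREM-like bouts > 15 min and
their first/last 10%. The long/short ripple-duration cutoff is a config
parameter, default 100 ms — it is a convention imported from prior work,
not derived here.

## Problem sizes and determinism

Default validation fixtures are 30-min recordings (60 min for state
scoring), with detector recovery averaged over 5 generator seeds and
noise-slope recovery over 20 seeds — sizes at which every acceptance
check is stable while the full suite and the acceptance script each run
in minutes on one CPU. Every stage is deterministic given config and
seed; rerunning a pipeline reproduces its CSV outputs byte for byte.
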