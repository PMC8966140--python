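# Methods

This package re-implements, as a tested pipeline, an analysis of listener
self-motion under hearing impairment and directional hearing aids: movement
measures derived from head/eye/torso trajectories, an acoustic simulation
that replays measured head motion through a virtual loudspeaker scene into
hearing-aid microphones, an adaptive differential microphone (ADM), and
better-ear segmental SNR estimation. A seeded synthetic generator stands in
for participant recordings, which are not publicly available. This note
documents the models, the parameters that matter, the numerical choices,
and what the synthetic conditions do and do not show about real data.

## Trajectory processing

**Sensor model.** Head yaw, horizontal head translation and torso yaw are
sampled at 200 Hz (motion tracking); horizontal eye-in-head azimuth comes
from an electrooculogram (EOG) at 33 Hz. Azimuths are in degrees, 0° dead
ahead, positive leftward (counterclockwise from above), wrapped to
(−180°, 180°].

**EOG drift correction.** EOG electrodes drift slowly. The drift estimate
is the calibrated EOG series, padded at both ends by linear extrapolation
of the first/last 250 samples, smoothed with a centered 500-sample moving
average (~15 s at 33 Hz), and subtracted. The padding is what makes a
centered 500-sample average defined over the whole support. Two properties
follow from linearity:

* random-walk drift is removed almost entirely once the record is long
  relative to the window (the residual variance is ≈ σ²·m/6 with m = 250,
  independent of record length, while the drift's path variance grows
  ≈ σ²N/6; at 600 s and σ = 0.05°/sample the expected removal is ≈ 99%,
  and the test suite verifies ≥ 95% as a median over seeds);
* the corrector also removes genuine eye-movement components slower than
  the window. Saccade *amplitudes* (local steps) survive within a few
  percent, but sustained lateral fixations are pulled toward zero. The
  consequences for the head-gaze ratio are discussed below.

**Fusion.** All streams are linearly interpolated onto a common 120 Hz
axis over the overlap of their supports, and gaze = head yaw +
eye-in-head, an exact sample-wise identity. No anti-alias filter is used
for the 200→120 Hz step; head motion is slow enough that aliasing is
negligible (documented limitation).

**Saccade detection.** Angular velocity is estimated by central
differences after a 50 ms moving-average smooth. Contiguous runs of
|velocity| above a threshold become events; events closer than 50 ms
merge; events smaller than 3° are dropped. Thresholds default to 50 deg/s
for the eye and gaze series and 20 deg/s for the head — standard
oculomotor/head-kinematics ranges — and are configurable, since the
original detection procedure is not fully specified in the source
literature.

## Movement measures

Per recording: GazeStd/HeadStd (sample standard deviation of the yaw
trajectories), GazeSpeedMean/HeadSpeedMean (mean |velocity|, same
estimator as detection, computed over the full series), NGazeJumps
(gaze-saccade count per minute), TargetGazeRMS/TargetHeadRMS (RMS of the
wrapped angular error to the piecewise-constant active-speaker track;
undefined in environments with no target).

**HeadGazeRatio** is the mean over samples of |head re torso| / |gaze re
torso| after three exclusions: (a) samples during a head or eye saccade
(the measure targets static orientation); (b) samples where the head
angle exceeds the gaze angle in magnitude or has opposite sign (the ratio
has no meaning there; head = 0 counts as same-sign because a ratio of 0
is meaningful all-eye behavior); (c) samples with |gaze re torso| < 10°
(noise-dominated, near-division-by-zero). Rule (b) confines the ratio to
[0, 1]. Per-sample ratios are averaged (not a ratio of means), which is
the reading consistent with per-sample exclusions. If no sample survives,
the ratio is undefined — a value, not an error. NGazeJumps is reported in
events per minute (the unit is a package choice, recorded in the table
metadata).

**Interaction between drift correction and HeadGazeRatio.** Because the
drift corrector attenuates eye components slower than its ~15 s window,
sustained lateral fixations shrink the measured eye angle and inflate the
ratio: with talkers at ±30° and ~5 s turns, recovered ratios for a true
head contribution γ = 0.3 come out near 0.44–0.49. This is a property of
the original correction method, not of the generator. Parameter-recovery
tests therefore use the centered-target paradigm (frontal target, brief
lateral glances — the lecture-hall-like situation), where the eye signal
is zero-mean at the smoother's timescale and recovery is unbiased
(measured 0.308/0.510/0.708/0.935 for γ = 0.3/0.5/0.7/0.94). Users
analyzing multi-talker recordings should treat absolute ratio values with
this bias in mind; group *contrasts* under a shared paradigm are less
affected.

## Scene rendering

Sources are amplitude-panned onto a 29-direction virtual loudspeaker
layout: a 16-speaker horizontal ring at ear level (first direction
11.25°, 22.5° spacing, radius 1.76 m), rings of 6 at ±45° elevation
(starting 0° and 30°, 60° spacing), and one pole. Horizontal sources use
pairwise constant-power panning on the ring (energy conserved to ±0.1 dB
at any azimuth); elevated sources snap to the nearest direction. Target
and noise are rendered to separate channel sets; rendering is exactly
linear, so the parts sum to the mixture.

**Head motion.** Per 1024-sample block (the audio block size at
44.1 kHz), each ring channel — a world-fixed direction — is re-panned to
its direction as seen from the translated listener minus the head yaw,
with level scaled by the inverse distance ratio; elevated channels rotate
with nearest-direction snap; mixing matrices are linearly cross-faded
across each block to avoid clicks. A constant yaw of one ring slot
(22.5°) is an exact channel permutation; the rotate/unrotate round trip
is exact at slot multiples. At non-multiples the pairwise panning law
spreads energy to neighbor channels and the round trip is lossy — an
inherent property of amplitude panning, so identity tests use
slot-aligned yaws. Translation assumes the 1.76 m ring radius; its effect
is second-order for realistic sway.

**Head/hearing-aid impulse responses.** Measured impulse-response sets
can be loaded (one response per direction and microphone); the default is
a parametric model: per-ear Woodworth-style arrival delay from the
lateral coordinate ξ = sin(az)·cos(el) (head radius 8.75 cm), a
first-order low-pass head shadow on the far ear whose cutoff slides from
~10·f₀ (none) to f₀/10 at full contralateral incidence (f₀ = c/2πa ≈
624 Hz), and a front/rear microphone axial delay (d/c)·cos(az)·cos(el)
with d = 10 mm, so the front mic leads by exactly d/c ≈ 29.2 µs for
frontal sound. Delays are realized by 64-tap windowed-sinc fractional
filters; 64 taps (rather than 32) keep the downstream cardioid null below
−30 dB, which depends directly on delay accuracy. The model reproduces
the qualitative properties the pipeline depends on — ITD, head shadow,
mic-pair geometry — not any individual's responses.

## Adaptive differential microphone

Per side (left/right processed independently, no shared state): front and
rear omni microphone signals form front- and back-facing cardioids by
delay-and-subtract with the d/c delay; the output is y = c_front −
β·c_back with β adapted per 64-sample block by a normalized gradient
(NLMS) step toward minimum output power, hard-clipped to [0, 1] so the
steered null stays in the rear hemisphere. The exact update is a package
choice (the classical description constrains only the null region):
β ← clip(β + μ·⟨y·c_back⟩/(⟨c_back²⟩+ε)), μ = 10⁻² per block. Converged β
matches a brute-force power-minimizing grid search within 0.02.

**Compensation.** A bare differential output is tilted +6 dB/octave. A
first-order IIR low-pass equalizes it, with default cutoff 100 Hz — well
below the speech band, so across 200 Hz–8 kHz the filter operates in its
1/f region and flattens the tilt (frontal overall response within ±3 dB),
gain-matched to unity at 1 kHz. A cutoff near the differential transition
frequency c/2πd ≈ 5.5 kHz would leave the tilt in place across nearly the
whole band; hence the low default. Configurable.

**Shadow processing.** The recorded per-block β trajectory and filter
states define a time-varying *linear* system; replaying it on the clean
target and noise components separately yields outputs that sum to the
mixture output within float rounding (< 10⁻⁶ full scale), making SNR
after the adaptive algorithm well-defined.

**Anechoic benchmark.** With a frontal speech-shaped target and one rear
interferer at equal power, sweeping the interferer over the rear
hemisphere in 15° steps, the best better-ear segmental SNR improvement is
≈ 30 dB at 10 s duration (the null removes the interferer almost
entirely; per-window SNR is clamped at +35 dB). This comfortably clears
the ≥ 15 dB figure canonical for this algorithm class in anechoic
single-interferer conditions. Real multi-source, reverberant scenes yield
improvements orders of magnitude smaller (a few tenths of a dB), as the
pipeline's diffuse-babble scenes show.

## SNR estimation

Better-ear segmental SNR: separately rendered clean target and noise per
ear, non-overlapping 200 ms windows, per window 10·log₁₀(Σt²/Σn²) clamped
to [−10, +35] dB (the usual segmental convention; the clamp is
configurable, and silent-noise windows clamp high rather than erroring),
better ear = per-window max of left/right, scalar = mean over windows.
Better-ear selection is per window, independently in each condition, so
comparisons are well defined. SNRrelative = mean window-wise difference
between the motion and no-motion (head fixed frontal) tracks — exactly 0
for the no-motion trajectory. SNRimprovementADM = mean window-wise
better-ear difference between shadow-processed ADM outputs and the
unprocessed front-microphone pair (the unaided listening path).

## Synthetic study conditions

The generator emulates the statistical structure the analysis assumes:

* **Scenes.** Multi-talker conversations: exponential speaker turns (mean
  5 s) over fixed talker azimuths, never repeating a speaker; diffuse
  babble as 16 independent speech-shaped noise sources spread over the
  ring; babble gain calibrated so the no-motion reference better-ear SNR
  hits a requested value (±0.3 dB, via re-measurement through the full
  microphone pipeline). Speech is speech-shaped noise with 4 Hz raised-
  cosine syllabic modulation — SNR measures need only power structure;
  real recordings can be substituted.
* **Behavior.** Gaze saccades (raised-cosine profile, main-sequence-like
  duration 30 ms + 2 ms/deg) toward each new active speaker after a
  sampled latency (mean 0.25 s, sd 0.05 s); distractor glances at ~2 per
  minute; head = γ·gaze plus tremor, so head re torso = γ·gaze re torso
  holds during fixations by construction; eye = gaze − head. Sensors:
  head at 200 Hz with 0.3° low-passed tremor; EOG at 33 Hz with 1° white
  noise plus a 0.05°/sample random-walk drift. Shipped group profiles set
  γ = 0.60 (younger normal-hearing), 0.75 (older normal-hearing), 0.94
  (hearing-impaired) — only the 0.94 magnitude traces to reported group
  behavior; the others are free parameters chosen to reproduce the
  ordering younger < older < impaired.
* **What passing tests do not show.** The generator has no reverberation,
  no Lombard speech, no visual scene, no torso movement, and no
  translation; SNRrelative magnitudes and signs from synthetic behavior
  need not match those measured from real participants (in these scenes,
  target-following head motion can *lower* the better-ear SNR relative to
  facing front). Tests establish that the pipeline's operations are
  correct and self-consistent, not that synthetic listeners behave like
  real ones.

Everything is reproducible bit-for-bit from (seed, parameters); per-cell
seeds are derived arithmetically from the run seed and stay below 2³¹.

## Statistics

Mixed ANOVA per measure: listener group between participants,
environment within, fitted via pingouin; Greenhouse-Geisser-corrected
degrees of freedom and p when Mauchly's test rejects sphericity at 0.05;
effect size is partial η². The family for Benjamini-Hochberg false-
discovery-rate control is all group and interaction p-values of the
ANOVAs run in one invocation. Pairwise group comparisons within each
environment use two-sample t tests with Bonferroni correction, the family
being the pairs tested within that environment. Participants missing a
measure in more than half the environments are excluded listwise for that
measure, with a warning; a constant dependent variable short-circuits to
F = 0, p = 1. Sum-of-squares conventions follow pingouin's mixed-model
decomposition; the between-factor F is cross-checked in the tests against
a from-scratch sums-of-squares computation.

## Problem sizes

Default test/demo sizes are chosen for desk-scale runs: scenes at 16 kHz
(the parametric impulse-response model requires ≥ 8 kHz to resolve the
29 µs mic delay), 20–30 s per environment for acoustic runs, 120 s
trajectories for movement measures, 10 s at 44.1 kHz for the ADM
benchmark. All sizes are configuration fields.

## Known limitations

* Broadband (not per-band) adaptive weight; commercial implementations
  are often per-band.
* No room reverberation or source movement Doppler; the no-motion
  reference and rotation identities rely on the anechoic panning model.
* The parametric impulse responses are a caricature; absolute SNR levels
  (e.g. reference SNRs per environment) depend on them and on the clamp
  convention, so only within-pipeline contrasts are meaningful.
* Speeds are computed over the full series including saccades; whether
  the original analyses excluded saccade samples for speed measures is
  not recoverable, and the choice is documented here.
* The EOG drift corrector biases HeadGazeRatio upward under sustained
  lateral fixation (see above); this affects any analysis using this
  correction method, including the original.
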