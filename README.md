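# selfmotion

Analysis of listener self-motion and its acoustic consequences for
hearing-device users: trajectory-derived movement measures, head-motion
driven acoustic simulation to hearing-aid microphones, an adaptive
differential microphone (ADM), and better-ear segmental SNR estimation —
with a seeded synthetic behavior-and-scene generator so the whole pipeline
runs and is testable without any participant recordings.

## Who this is for

Researchers in computational audiology and hearing-device signal
processing who want to quantify how head and eye movement behavior
interacts with directional microphone algorithms: how much of a gaze
reorientation is carried by the head versus the eyes, what a measured (or
simulated) head-motion trajectory does to the signal-to-noise ratio at
the ears, and how much a front/rear-microphone adaptive beamformer would
have helped along that trajectory.

## The models in brief

**Gaze decomposition.** Head yaw (200 Hz motion tracking) and horizontal
eye-in-head azimuth from EOG (33 Hz, drift-corrected by subtracting a
centered 500-sample moving average of the linearly extrapolated series)
are resampled to a common 120 Hz timeline and summed: gaze = head + eye.
Movement measures include the **HeadGazeRatio** — the mean over fixation
samples of |head re torso| / |gaze re torso| with three exclusions
(saccade samples; head larger than gaze or of opposite sign; |gaze| <
10°) — which is 1 for all-head and 0 for all-eye reorienting.

**Acoustic path.** Scenes (target + noise sources, active-speaker
schedule) are amplitude-panned onto a 29-direction virtual loudspeaker
layout; the measured head yaw/translation rotates and shifts the virtual
listener per 1024-sample block; direction channels are convolved with
head/hearing-aid impulse responses (a parametric model by default,
measured sets loadable) into 4 microphone signals (left/right ×
front/rear), separately for target and noise.

**ADM.** Per side, front/back cardioids are formed by delay-and-subtract
(delay d/c for mic spacing d = 10 mm) and combined as y = c_front −
β·c_back, with β adapted block-wise (NLMS) to minimize output power,
clipped to [0, 1] so the steered null stays behind the listener. The
recorded β trajectory is replayed on the clean target and noise
separately (**shadow filtering**), so the SNR after this adaptive,
data-dependent algorithm is well-defined: the component outputs sum to
the mixture output to float precision.

**SNR.** Better-ear segmental SNR: per 200 ms window and ear,
10·log₁₀(Σtarget²/Σnoise²) clamped to [−10, +35] dB, better ear = max of
the two, averaged over windows. **SNRrelative** compares a motion
trajectory against the head-fixed-frontal reference window-by-window;
**SNRimprovementADM** compares ADM outputs against the unprocessed
front-microphone pair.

**Statistics.** Mixed ANOVAs (group between, environment within,
Greenhouse-Geisser correction when sphericity fails, partial η²),
Benjamini-Hochberg control across the family of ANOVA p-values, and
Bonferroni-corrected pairwise group comparisons per environment.

See `docs/methods.md` for assumptions, parameter defaults, numerical
choices, and known limitations.

## Worked example

```python
import numpy as np
from selfmotion import (BehaviorProfile, TargetTrack, generate_behavior,
                        fuse, compute_all)
from selfmotion.benchmark import adm_rear_interferer_benchmark

# a lecture-like situation: frontal target, occasional lateral glances
target = TargetTrack(np.array([0.0, 120.0]), np.array([0.0, 0.0]))
profile = BehaviorProfile(head_contribution=0.94)   # hearing-impaired-like
ds = generate_behavior(target, profile, duration=120.0, seed=1)

g = fuse(ds.recording)          # drift-correct, resample to 120 Hz, fuse
m = compute_all(g, target)
print(f"HeadGazeRatio = {m.HeadGazeRatio:.3f}  "
      f"(true gamma = {ds.gamma}, {m.excluded_fraction:.0%} of samples excluded)")
print(f"NGazeJumps    = {m.NGazeJumps:.2f} per minute")
print(f"TargetGazeRMS = {m.TargetGazeRMS:.2f} deg")

res = adm_rear_interferer_benchmark(seed=1, duration=4.0)
print(f"ADM benchmark: best improvement {res['best_improvement']:.1f} dB "
      f"at interferer azimuth {res['best_angle']:.0f} deg")
```

prints

```
HeadGazeRatio = 0.937  (true gamma = 0.94, 99% of samples excluded)
NGazeJumps    = 13.50 per minute
TargetGazeRMS = 2.41 deg
ADM benchmark: best improvement 33.4 dB at interferer azimuth 165 deg
```

The recovered HeadGazeRatio matches the generator's head-contribution
parameter (0.94: almost all of the reorienting done with the head); the
exclusion rules keep only non-saccadic samples with |gaze| ≥ 10°, which
in a frontal-target situation means the brief lateral glances. The ADM
benchmark places a single interferer behind the listener at the angle its
steered null can best reach and reports the better-ear segmental SNR gain
— tens of dB in this anechoic single-interferer configuration, versus
tenths of dB in diffuse multi-talker scenes.

## Command line

```sh
selfmotion generate  --seed 1 --output-dir out     # trajectory files + ground truth
selfmotion measures  --seed 1 --output-dir out     # tidy movement-measure table
selfmotion acoustics --seed 1 --output-dir out     # SNRrelative / SNRimprovementADM
selfmotion stats --measures-csv out/measures.csv --acoustics-csv out/acoustics.csv
selfmotion all --seed 1 --output-dir out           # everything
```

A YAML config (`--config`) controls environments, group profiles, sample
rates, durations, ADM and SNR parameters; a run's config + seed
reproduces its outputs exactly.

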