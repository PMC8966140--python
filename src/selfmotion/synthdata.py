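"""Seeded generator of listener behavior and multi-talker scenes.

The study conditions this package analyzes pair (a) multi-talker scenes —
an active speaker moving between fixed talker azimuths with diffuse
babble — with (b) listener self-motion: gaze saccades toward each new
active speaker after a reaction latency, with a controllable fraction
gamma of the torso-relative gaze angle carried by the head during
fixations (the head-gaze ratio), plus realistic sensor imperfections
(200 Hz head tracking with tremor, 33 Hz EOG with additive noise and
random-walk drift).

The generator emulates the statistical structure the analysis pipeline
assumes, not the content of any real recording: speech is a speech-shaped
noise surrogate with 4 Hz syllabic amplitude modulation, and ground truth
(noise-free gaze, true saccade events, true gamma) is stored so every
pipeline stage can be tested for parameter recovery.  Output is
bit-reproducible given (seed, profile, scene parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .measures import TargetTrack
from .scene import ArrayLayout, HarirModel, ParametricHarir, SceneSpec, Source
from .snr import reference_snr
from .trajectories import MotionRecording, SaccadeEvent

__all__ = [
    "BehaviorProfile",
    "GeneratedDataset",
    "PROFILES",
    "speech_shaped_noise",
    "generate_conversation_scene",
    "generate_behavior",
]


@dataclass(frozen=True)
class BehaviorProfile:
    """Parameters of one listener-group behavior style.

    ``head_contribution`` (gamma) is the fraction of the torso-relative
    gaze angle carried by the head during fixations; the shipped profiles
    put it at 0.60 (younger normal-hearing), 0.75 (older normal-hearing)
    and 0.94 (hearing-impaired), reproducing the ordering younger < older
    < hearing-impaired.  Sensor-noise defaults: 1 deg EOG noise (the
    sensor's ~+-10 deg absolute accuracy is dominated by drift, handled
    separately), 0.05 deg/sample random-walk drift, 0.3 deg head tremor.
    """

    head_contribution: float = 0.75  # gamma in [0, 1]
    gaze_reaction_latency: float = 0.25  # s, mean
    latency_jitter: float = 0.05  # s, sd
    saccade_rate_scale: float = 1.0  # scales distractor-glance rate
    eog_noise_sigma: float = 1.0  # deg
    eog_drift_step_sigma: float = 0.05  # deg per 33 Hz sample
    head_tremor_sigma: float = 0.3  # deg
    undershoot: float = 0.0  # deg, gaze lands short of the target

    def __post_init__(self) -> None:
        if not 0.0 <= self.head_contribution <= 1.0:
            raise ValueError("head_contribution must lie in [0, 1]")
        for name in ("eog_noise_sigma", "eog_drift_step_sigma",
                     "head_tremor_sigma", "latency_jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


PROFILES = {
    "NH_young": BehaviorProfile(head_contribution=0.60),
    "NH_old": BehaviorProfile(head_contribution=0.75),
    "HI": BehaviorProfile(head_contribution=0.94),
}


@dataclass
class GeneratedDataset:
    """A synthetic recording plus the ground truth behind it."""

    recording: MotionRecording
    truth_t: np.ndarray  # master 200 Hz time axis
    truth_gaze: np.ndarray  # noise-free gaze, deg
    truth_head: np.ndarray  # noise-free head yaw, deg
    true_events: list  # ground-truth gaze SaccadeEvents
    gamma: float
    profile: BehaviorProfile
    seed: int
    target: Optional[TargetTrack] = None
    scene: Optional[SceneSpec] = None


# ---------------------------------------------------------------------------
# Audio surrogates


def speech_shaped_noise(n: int, fs: int, rng: np.random.Generator,
                        modulated: bool = True, mod_rate: float = 4.0,
                        mod_depth: float = 0.8) -> np.ndarray:
    """Speech-shaped stationary noise, optionally 4 Hz syllabically
    amplitude-modulated; unit RMS.

    The long-term spectrum rises to a broad maximum near 500 Hz and falls
    ~6 dB/octave above it, a stock long-term-average-speech-spectrum
    shape; only the power structure matters for the SNR measures.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = (f / 120.0) / (1.0 + (f / 120.0) ** 2) ** 0.5  # high-pass knee
    shape *= 1.0 / (1.0 + (f / 600.0) ** 2) ** 0.5  # -6 dB/oct above 600 Hz
    x = np.fft.irfft(spec * shape, n=n)
    if modulated:
        t = np.arange(n) / fs
        phase = rng.uniform(0.0, 2.0 * np.pi)
        env = 1.0 + mod_depth * np.sin(2.0 * np.pi * mod_rate * t + phase)
        x = x * env
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


# ---------------------------------------------------------------------------
# Scenes


def generate_conversation_scene(
    n_talkers: int,
    azimuths: Sequence[float],
    turn_mean: float,
    duration: float,
    seed: int,
    babble_sources: int = 16,
    snr_db: float = 0.0,
    sample_rate: int = 16000,
    model: Optional[HarirModel] = None,
    layout: Optional[ArrayLayout] = None,
    calibrate: bool = True,
    calibration_iters: int = 2,
) -> tuple[SceneSpec, TargetTrack]:
    """A multi-talker conversation in diffuse babble.

    Speaker turns have exponential durations (mean ``turn_mean`` s) over
    the given talker azimuths, never handing over to the same talker
    twice in a row; the target role follows the active speaker.  The
    babble is ``babble_sources`` mutually independent speech-shaped noise
    sources spread evenly over the ear-level ring.  When ``calibrate`` is
    true the babble gain is adjusted (by re-measuring the no-motion
    reference through the full microphone pipeline) until the reference
    better-ear SNR equals ``snr_db``.

    Returns the scene plus the piecewise-constant target azimuth track.
    """
    if n_talkers < 1:
        raise ValueError("need at least one talker")
    azimuths = list(azimuths)[:n_talkers]
    if len(azimuths) == 0:
        raise ValueError("empty talker azimuth list")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))

    # speaker-turn schedule
    schedule: list[tuple[float, float, int]] = []
    t = 0.0
    prev = -1
    while t < duration:
        dur = rng.exponential(turn_mean)
        choices = [i for i in range(len(azimuths)) if i != prev]
        idx = int(rng.choice(choices)) if choices else 0
        schedule.append((t, min(t + dur, duration), idx))
        prev = idx
        t += dur

    # gated talker signals with 10 ms raised-cosine ramps
    ramp = int(0.01 * sample_rate)
    gates = [np.zeros(n) for _ in azimuths]
    for t0, t1, idx in schedule:
        i0, i1 = int(t0 * sample_rate), int(t1 * sample_rate)
        g = np.ones(i1 - i0)
        r = min(ramp, len(g) // 2)
        if r > 0:
            fade = 0.5 * (1.0 - np.cos(np.linspace(0.0, np.pi, r)))
            g[:r] *= fade
            g[-r:] *= fade[::-1]
        gates[idx][i0:i1] = np.maximum(gates[idx][i0:i1], g)

    sources = []
    for i, az in enumerate(azimuths):
        sig = speech_shaped_noise(n, sample_rate, rng) * gates[i]
        sources.append(Source(signal=sig, azimuth=float(az), role="target"))

    babble_az = np.arange(babble_sources) * 360.0 / babble_sources
    for az in babble_az:
        sig = speech_shaped_noise(n, sample_rate, rng, modulated=False)
        sources.append(Source(signal=sig, azimuth=float(az), role="noise",
                              gain_db=-10.0 * np.log10(babble_sources)))

    spec = SceneSpec(sources=sources, duration=duration,
                     sample_rate=sample_rate,
                     active_speaker_schedule=schedule)

    track_t = np.array([s[0] for s in schedule])
    track_az = np.array([azimuths[s[2]] for s in schedule], dtype=float)
    target = TargetTrack(t=track_t, target_azimuth=track_az, defined=True)

    if calibrate:
        model = model or ParametricHarir(fs=sample_rate)
        for _ in range(calibration_iters):
            ref, _ = reference_snr(spec, model, layout=layout)
            delta = ref - snr_db
            if abs(delta) < 0.05:
                break
            for s in spec.sources:
                if s.role == "noise":
                    s.gain_db += delta
    return spec, target


# ---------------------------------------------------------------------------
# Behavior


def _saccade_profile(amplitude: float) -> float:
    """Saccade duration from amplitude (main-sequence-like: 30 ms plus
    2 ms per degree)."""
    return 0.03 + 0.002 * abs(amplitude)


def generate_behavior(
    target: TargetTrack,
    profile: BehaviorProfile,
    duration: float,
    seed: int,
    f_head: float = 200.0,
    f_eog: float = 33.0,
    participant_id: str = "synthetic",
    environment_id: str = "synthetic",
    group: str = "NH_old",
) -> GeneratedDataset:
    """Synthesize one recording of gaze-following behavior.

    The noise-free gaze holds the current target azimuth and executes a
    smooth (raised-cosine) saccade toward each new one after a sampled
    reaction latency; distractor glances (brief looks at a random nearby
    azimuth and back) occur at ~2 per minute times
    ``profile.saccade_rate_scale``.  The head carries
    ``gamma = profile.head_contribution`` of the gaze angle —
    ``head = gamma * gaze`` plus tremor — so during fixations
    ``head_re_torso = gamma * gaze_re_torso`` holds by construction
    (torso fixed at 0).  Sensor streams: head yaw at ``f_head`` with
    tremor, EOG (= gaze - head) at ``f_eog`` with additive white noise
    and random-walk drift.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * f_head)) + 1
    t = np.arange(n) / f_head

    # fixation plan: (time, kind, value) knots; kind "target" carries an
    # absolute azimuth, "glance" a relative offset, "return" goes back to
    # the current target
    az0 = float(target.at(np.array([0.0]))[0]) if target.defined else 0.0
    knots: list[tuple[float, str, float]] = []
    if target.defined:
        change_idx = np.flatnonzero(np.diff(target.target_azimuth) != 0) + 1
        for i in change_idx:
            t_change = float(target.t[i])
            if t_change >= duration:
                continue
            latency = max(0.05, rng.normal(profile.gaze_reaction_latency,
                                           profile.latency_jitter))
            knots.append((t_change + latency, "target",
                          float(target.target_azimuth[i])))

    # distractor glances: look away and back
    rate_per_s = 2.0 / 60.0 * profile.saccade_rate_scale
    n_glances = rng.poisson(rate_per_s * duration) if rate_per_s > 0 else 0
    for _ in range(n_glances):
        tg = rng.uniform(1.0, max(1.5, duration - 1.5))
        offset = rng.uniform(10.0, 40.0) * rng.choice([-1.0, 1.0])
        hold = rng.uniform(0.4, 0.8)
        knots.append((tg, "glance", offset))
        knots.append((tg + hold, "return", 0.0))

    knots.sort(key=lambda k: k[0])

    # build the noise-free gaze with raised-cosine saccades
    gaze = np.empty(n)
    current = az0
    gaze[:] = current
    events: list[SaccadeEvent] = []
    target_now = az0
    for tk, kind, value in knots:
        if kind == "target":
            dest = value
            target_now = value
        elif kind == "glance":
            dest = current + value
        else:
            dest = target_now
        if profile.undershoot != 0.0 and dest != current:
            dest = dest - np.sign(dest - current) * min(
                profile.undershoot, abs(dest - current) / 2.0)
        amp = dest - current
        if abs(amp) < 1e-9:
            continue
        dur = _saccade_profile(amp)
        i0 = int(np.searchsorted(t, tk))
        i1 = int(np.searchsorted(t, tk + dur))
        if i0 >= n:
            break
        i1 = min(max(i1, i0 + 2), n)
        phase = np.linspace(0.0, np.pi, i1 - i0)
        gaze[i0:i1] = current + amp * 0.5 * (1.0 - np.cos(phase))
        gaze[i1:] = dest
        events.append(SaccadeEvent(onset=t[i0], offset=t[min(i1, n - 1)],
                                   amplitude=abs(amp), effector="gaze"))
        current = dest

    gamma = profile.head_contribution
    head_clean = gamma * gaze
    eye_clean = gaze - head_clean

    # head tremor: low-passed white noise rescaled to the target sd
    tremor = rng.standard_normal(n)
    k = max(1, int(0.1 * f_head))
    tremor = np.convolve(tremor, np.full(k, 1.0 / k), mode="same")
    sd = np.std(tremor)
    if sd > 0 and profile.head_tremor_sigma > 0:
        tremor *= profile.head_tremor_sigma / sd
    else:
        tremor[:] = 0.0
    head_meas = head_clean + tremor

    # EOG at 33 Hz: additive noise + random-walk drift
    n_eog = int(round(duration * f_eog)) + 1
    t_eog = np.arange(n_eog) / f_eog
    eye_at_eog = np.interp(t_eog, t, eye_clean)
    eog = eye_at_eog + rng.normal(0.0, profile.eog_noise_sigma, n_eog)
    eog += np.cumsum(rng.normal(0.0, profile.eog_drift_step_sigma, n_eog))

    rec = MotionRecording(
        t_head=t, head_yaw=head_meas,
        head_translation_xy=np.zeros((n, 2)),
        torso_yaw=np.zeros(n),
        t_eog=t_eog, eog_raw=eog,
        participant_id=participant_id, environment_id=environment_id,
        group=group,
    )
    return GeneratedDataset(
        recording=rec, truth_t=t, truth_gaze=gaze, truth_head=head_clean,
        true_events=events, gamma=gamma, profile=profile, seed=seed,
        target=target,
    )
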