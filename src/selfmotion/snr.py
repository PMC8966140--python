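"""Better-ear segmental SNR, the no-motion reference, and ADM improvement.

SNRs are computed from separately rendered clean target and noise
components in non-overlapping 200 ms windows, per ear, clamped per window
(default [-10, +35] dB, the usual segmental-SNR convention), and the
better ear is the per-window maximum of the two.  Scalar summaries:

* ``SNRrelative`` — mean window-wise difference between the SNR under a
  measured head-motion trajectory and the SNR with the head fixed facing
  front (the no-motion reference).
* ``SNRimprovementADM`` — mean window-wise difference between the
  better-ear SNR of the ADM outputs (shadow-filtered components) and that
  of the unprocessed front-microphone pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .adm import AdmConfig, process_binaural
from .scene import (ArrayLayout, HaMicSignals, HarirModel, HeadPose,
                    SceneSpec, apply_head_motion, render_to_array, to_ha_mics)

__all__ = [
    "SnrTrack",
    "SnrSummary",
    "segmental_snr",
    "better_ear_track",
    "render_scene_to_mics",
    "reference_snr",
    "snr_relative",
    "snr_improvement_adm",
    "WINDOW_LEN",
    "CLAMP",
]

WINDOW_LEN = 0.2  # s, non-overlapping analysis windows
CLAMP = (-10.0, 35.0)  # dB, per-window segmental-SNR limits


@dataclass
class SnrTrack:
    """Per-window per-ear SNR values plus the better-ear track."""

    left: np.ndarray  # dB per window
    right: np.ndarray
    window_len: float
    clamp: tuple[float, float]

    @property
    def better_ear(self) -> np.ndarray:
        return np.maximum(self.left, self.right)

    @property
    def mean(self) -> float:
        return float(np.mean(self.better_ear))

    @property
    def n_windows(self) -> int:
        return self.left.size


@dataclass
class SnrSummary:
    SNRrelative: Optional[float]  # dB
    SNRimprovementADM: Optional[float]  # dB
    reference_snr: Optional[float]  # dB


def _window_snr_db(target: np.ndarray, noise: np.ndarray, n_win: int,
                   win: int, clamp: tuple[float, float]) -> np.ndarray:
    t2 = target[: n_win * win].reshape(n_win, win)
    n2 = noise[: n_win * win].reshape(n_win, win)
    pt = np.sum(t2 ** 2, axis=1)
    pn = np.sum(n2 ** 2, axis=1)
    out = np.empty(n_win)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = 10.0 * np.log10(pt / pn)
    # silent-noise windows clamp high; silent-target windows clamp low
    out = np.where(pn == 0.0, clamp[1], ratio)
    out = np.where((pn > 0.0) & (pt == 0.0), clamp[0], out)
    return np.clip(out, clamp[0], clamp[1])


def segmental_snr(target: HaMicSignals | tuple, noise: HaMicSignals | tuple,
                  sample_rate: Optional[int] = None,
                  window_len: float = WINDOW_LEN,
                  clamp: tuple[float, float] = CLAMP,
                  ears: tuple[str, str] = ("left_front", "right_front")
                  ) -> SnrTrack:
    """Better-ear segmental SNR from clean target and noise components.

    ``target``/``noise`` are either :class:`HaMicSignals` (the channels in
    ``ears``, default front mics, act as the ear signals) or plain
    ``(left, right)`` array pairs with ``sample_rate`` given.  Per window
    and ear the SNR is ``10 log10(sum t^2 / sum n^2)``, clamped; windows
    are non-overlapping and a trailing partial window is dropped.
    """
    if isinstance(target, HaMicSignals):
        fs = target.sample_rate
        tl, tr = getattr(target, ears[0]), getattr(target, ears[1])
        nl, nr = getattr(noise, ears[0]), getattr(noise, ears[1])
    else:
        if sample_rate is None:
            raise ValueError("sample_rate required for array input")
        fs = sample_rate
        tl, tr = target
        nl, nr = noise
    win = int(round(window_len * fs))
    if win < 1 or len(tl) < win:
        raise ValueError("signal shorter than one analysis window")
    n_win = len(tl) // win
    left = _window_snr_db(tl, nl, n_win, win, clamp)
    right = _window_snr_db(tr, nr, n_win, win, clamp)
    return SnrTrack(left=left, right=right, window_len=window_len, clamp=clamp)


def better_ear_track(track: SnrTrack) -> np.ndarray:
    return track.better_ear


def render_scene_to_mics(spec: SceneSpec, model: HarirModel,
                         pose: Optional[HeadPose] = None,
                         layout: Optional[ArrayLayout] = None
                         ) -> tuple[HaMicSignals, HaMicSignals]:
    """Full scene -> (target, noise) hearing-aid microphone signals.

    Renders to the loudspeaker layout, applies the head pose (no motion
    when ``pose`` is None), and convolves with the HARIR model — target
    and noise kept separate throughout.
    """
    layout = layout or ArrayLayout.default()
    channels = render_to_array(spec, layout)
    if pose is not None:
        for role in channels:
            channels[role] = apply_head_motion(
                channels[role], pose, layout, fs=spec.sample_rate)
    target = to_ha_mics(channels["target"], layout, model, component="target")
    noise = to_ha_mics(channels["noise"], layout, model, component="noise")
    return target, noise


def reference_snr(spec: SceneSpec, model: HarirModel,
                  layout: Optional[ArrayLayout] = None,
                  window_len: float = WINDOW_LEN,
                  clamp: tuple[float, float] = CLAMP) -> tuple[float, SnrTrack]:
    """Scalar mean better-ear SNR with the head fixed facing front, plus
    the per-window reference track for window-wise differencing."""
    target, noise = render_scene_to_mics(spec, model, pose=None, layout=layout)
    track = segmental_snr(target, noise, window_len=window_len, clamp=clamp)
    return track.mean, track


def snr_relative(track_with_motion: SnrTrack, reference: SnrTrack) -> float:
    """Mean window-wise better-ear SNR difference, motion minus reference.

    Exactly 0 when the two tracks coincide (the no-motion trajectory)."""
    n = min(track_with_motion.n_windows, reference.n_windows)
    return float(np.mean(track_with_motion.better_ear[:n]
                         - reference.better_ear[:n]))


def snr_improvement_adm(target: HaMicSignals, noise: HaMicSignals,
                        cfg: AdmConfig, window_len: float = WINDOW_LEN,
                        clamp: tuple[float, float] = CLAMP) -> dict:
    """Better-ear segmental SNR gain of the ADM via shadow processing.

    The ADM adapts on the mixture per side; the recorded state is replayed
    on the clean components; improvement is the mean window-wise better-ear
    SNR difference, processed minus unprocessed (front-mic pair).

    Returns a dict with ``improvement`` (dB), the processed and
    unprocessed :class:`SnrTrack` objects, and the per-side ADM results.
    """
    fs = target.sample_rate
    sides = process_binaural(target, noise, cfg)
    unproc = segmental_snr(target, noise, window_len=window_len, clamp=clamp)
    proc = segmental_snr(
        (sides["left"]["y_target"], sides["right"]["y_target"]),
        (sides["left"]["y_noise"], sides["right"]["y_noise"]),
        sample_rate=fs, window_len=window_len, clamp=clamp)
    n = min(proc.n_windows, unproc.n_windows)
    improvement = float(np.mean(proc.better_ear[:n] - unproc.better_ear[:n]))
    return {"improvement": improvement, "processed": proc,
            "unprocessed": unproc, "sides": sides}
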