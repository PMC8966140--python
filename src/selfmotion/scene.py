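"""Virtual acoustic scene rendering to hearing-aid microphones.

The rendering chain mirrors a loudspeaker-array based lab setup: each
source is amplitude-panned onto a 29-direction virtual loudspeaker layout
(horizontal ring of 16 at ear level, rings of 6 at +-45 deg elevation, one
pole), the listener's measured head yaw and translation are applied by
re-panning the ring channels per processing block, and the resulting
direction channels are convolved with head- and hearing-aid-related
impulse responses (HARIRs) to give 4-channel microphone signals
(left/right x front/rear), separately for target and noise so SNRs remain
computable.

Measured HARIRs can be supplied; by default a parametric model provides
them: fractional-delay impulses with a Woodworth-style interaural delay,
a first-order low-pass head shadow on the far ear, and a front/rear mic
axial delay of d/c * cos(incidence).

Convention: azimuth 0 = front, positive = left (counterclockwise from
above); x-axis points front, y-axis left.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.signal import fftconvolve

from ._angles import ang_diff_deg, wrap_deg

__all__ = [
    "ArrayLayout",
    "Source",
    "SceneSpec",
    "HeadPose",
    "HaMicSignals",
    "HarirModel",
    "ParametricHarir",
    "MeasuredHarir",
    "parametric_harir",
    "render_to_array",
    "apply_head_motion",
    "to_ha_mics",
    "plane_wave_to_mics",
    "MICS",
    "BLOCK_SIZE",
    "RING_RADIUS",
]

MICS = ("left_front", "left_rear", "right_front", "right_rear")
BLOCK_SIZE = 1024  # samples per motion-update block at 44.1 kHz
RING_RADIUS = 1.76  # m, horizontal loudspeaker ring radius


@dataclass
class ArrayLayout:
    """Virtual loudspeaker directions (azimuth, elevation) in degrees."""

    azimuths: np.ndarray
    elevations: np.ndarray

    def __post_init__(self) -> None:
        self.azimuths = wrap_deg(np.asarray(self.azimuths, dtype=float))
        self.elevations = np.asarray(self.elevations, dtype=float)
        if self.azimuths.shape != self.elevations.shape:
            raise ValueError("azimuth/elevation shape mismatch")

    @classmethod
    def default(cls) -> "ArrayLayout":
        """The 29-direction layout: 16-ring at ear level (first direction
        at 11.25 deg, 22.5 deg spacing), rings of 6 at +45 deg (starting
        0 deg) and -45 deg (starting 30 deg) with 60 deg spacing, and one
        pole at +90 deg elevation."""
        az = [11.25 + 22.5 * k for k in range(16)]
        el = [0.0] * 16
        az += [0.0 + 60.0 * k for k in range(6)]
        el += [45.0] * 6
        az += [30.0 + 60.0 * k for k in range(6)]
        el += [-45.0] * 6
        az += [0.0]
        el += [90.0]
        return cls(np.array(az), np.array(el))

    @property
    def n(self) -> int:
        return self.azimuths.size

    @property
    def ring(self) -> np.ndarray:
        """Indices of the ear-level ring, ordered by azimuth."""
        idx = np.flatnonzero(self.elevations == 0.0)
        return idx[np.argsort(self.azimuths[idx])]


@dataclass
class Source:
    """One scene source: a signal at an azimuth (static or a track)."""

    signal: np.ndarray
    azimuth: float | tuple[np.ndarray, np.ndarray]  # deg, or (t, az) track
    role: str = "noise"  # "target" | "noise"
    distance: float = RING_RADIUS  # m
    elevation: float = 0.0  # deg
    gain_db: float = 0.0

    def azimuth_at(self, t: np.ndarray) -> np.ndarray:
        if np.isscalar(self.azimuth):
            return np.full(np.shape(t), float(self.azimuth))
        tt, az = self.azimuth
        idx = np.clip(np.searchsorted(tt, t, side="right") - 1, 0, None)
        return np.asarray(az, dtype=float)[idx]


@dataclass
class SceneSpec:
    """Target and noise sources plus the active-speaker schedule."""

    sources: list
    duration: float  # s
    sample_rate: int = 44100
    active_speaker_schedule: list = field(default_factory=list)  # (t0, t1, idx)

    def __post_init__(self) -> None:
        if not any(s.role == "noise" for s in self.sources):
            raise ValueError("a scene needs at least one noise source")
        ends = sorted(self.active_speaker_schedule)
        for (a0, a1, _), (b0, _, _) in zip(ends, ends[1:]):
            if b0 < a1:
                raise ValueError("active-speaker intervals overlap")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate))


@dataclass
class HeadPose:
    """Head yaw (deg) and horizontal translation (m) over time."""

    t: np.ndarray
    yaw: np.ndarray
    translation_xy: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.yaw = np.asarray(self.yaw, dtype=float)
        self.translation_xy = np.atleast_2d(
            np.asarray(self.translation_xy, dtype=float))

    @classmethod
    def still(cls, duration: float) -> "HeadPose":
        """The no-motion pose: head fixed facing front."""
        t = np.array([0.0, duration])
        return cls(t, np.zeros(2), np.zeros((2, 2)))

    def sample(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        yaw = np.interp(t, self.t, self.yaw)
        tx = np.interp(t, self.t, self.translation_xy[:, 0])
        ty = np.interp(t, self.t, self.translation_xy[:, 1])
        return yaw, np.stack([tx, ty], axis=-1)


@dataclass
class HaMicSignals:
    """4-channel hearing-aid microphone audio for one scene component."""

    left_front: np.ndarray
    left_rear: np.ndarray
    right_front: np.ndarray
    right_rear: np.ndarray
    sample_rate: int
    component: str = "mixture"  # "target" | "noise" | "mixture"

    def __post_init__(self) -> None:
        n = len(self.left_front)
        for m in MICS:
            if len(getattr(self, m)) != n:
                raise ValueError("microphone channel lengths differ")

    def __add__(self, other: "HaMicSignals") -> "HaMicSignals":
        return HaMicSignals(
            *(getattr(self, m) + getattr(other, m) for m in MICS),
            sample_rate=self.sample_rate, component="mixture")

    def pair(self, side: str) -> tuple[np.ndarray, np.ndarray]:
        """(front, rear) pair for one side ("left" | "right")."""
        return getattr(self, f"{side}_front"), getattr(self, f"{side}_rear")


# ---------------------------------------------------------------------------
# HARIR models


class HarirModel:
    """Interface: an impulse response per (azimuth, elevation, mic)."""

    fs: int

    def ir(self, azimuth: float, elevation: float, mic: str) -> np.ndarray:
        raise NotImplementedError


def _fractional_delay(delay_samples: float, n_taps: int = 32) -> np.ndarray:
    """Windowed-sinc fractional-delay filter (Hann window).

    Contract: convolving with the returned filter delays the signal by
    ``n_taps // 2 + (delay_samples - round(delay_samples))`` samples;
    callers account for the remaining integer shift of
    ``round(delay_samples) - n_taps // 2``.
    """
    n = np.arange(n_taps)
    center = n_taps // 2
    frac = delay_samples - round(delay_samples)
    h = np.sinc(n - center - frac)
    h *= np.hanning(n_taps)
    h /= h.sum()
    return h


class ParametricHarir(HarirModel):
    """Parametric head/hearing-aid impulse-response model.

    A rigid-sphere caricature of a head wearing behind-the-ear devices:

    * per-ear arrival delay  tau_ear = (a/c) * (1 -+ xi)  with lateral
      coordinate xi = sin(az) cos(el) (positive left), a Woodworth-style
      interaural time difference of 2 a xi / c;
    * first-order low-pass head shadow on the far ear, cutoff sliding from
      ~10 * f0 (no shadow) down to f0/10 at full contralateral incidence,
      f0 = c / (2 pi a);
    * front/rear microphone axial delay (d/c) cos(az) cos(el), so the
      front mic leads the rear mic by exactly d/c for frontal sound;
    * elevation enters through the cos(el) projection only.

    Intended as a stand-in with the qualitative properties (ITD, head
    shadow, mic-pair geometry) that the downstream beamforming and
    better-ear SNR stages depend on; measured impulse responses can be
    substituted via :class:`MeasuredHarir`.
    """

    def __init__(self, fs: int, head_radius: float = 0.0875,
                 mic_spacing: float = 0.010, c: float = 343.0,
                 n_taps: int = 512, base_delay: float = 3e-3):
        if fs < 8000:
            raise ValueError(
                "sample rate below 8 kHz cannot resolve the d/c mic delay")
        self.fs = int(fs)
        self.head_radius = head_radius
        self.mic_spacing = mic_spacing
        self.c = c
        self.n_taps = n_taps
        self.base_delay = base_delay
        self._cache: dict = {}

    def ir(self, azimuth: float, elevation: float, mic: str) -> np.ndarray:
        key = (round(float(azimuth), 6), round(float(elevation), 6), mic)
        if key in self._cache:
            return self._cache[key]
        a, c, fs = self.head_radius, self.c, self.fs
        az = np.deg2rad(wrap_deg(azimuth))
        el = np.deg2rad(elevation)
        xi = np.sin(az) * np.cos(el)  # lateral coordinate, +1 = full left

        side, pos = mic.split("_")
        xi_side = xi if side == "left" else -xi
        tau_ear = (a / c) * (1.0 - xi_side)
        tau_mic = 0.0 if pos == "front" else (
            self.mic_spacing / c) * np.cos(az) * np.cos(el)
        delay = self.base_delay + tau_ear + tau_mic
        d_samp = delay * fs

        h = np.zeros(self.n_taps)
        frac = _fractional_delay(d_samp, n_taps=64)
        start = int(round(d_samp)) - len(frac) // 2
        for i, v in enumerate(frac):
            j = start + i
            if 0 <= j < self.n_taps:
                h[j] = v

        shadow = max(0.0, -xi_side)  # 0 ipsilateral .. 1 fully contralateral
        if shadow > 0.0:
            f0 = c / (2.0 * np.pi * a)
            fc = f0 * 10.0 ** (1.0 - 2.0 * shadow)
            alpha = np.exp(-2.0 * np.pi * fc / fs)
            lp = (1.0 - alpha) * alpha ** np.arange(self.n_taps)
            h = fftconvolve(h, lp)[: self.n_taps]
        self._cache[key] = h
        return h

    def shadow_gain_db(self, azimuth: float, elevation: float = 0.0) -> float:
        """Broadband level difference (dB, left minus right front mic) for
        a white input from the given direction — the model's head-shadow
        attenuation, evaluated from the IRs themselves."""
        hl = self.ir(azimuth, elevation, "left_front")
        hr = self.ir(azimuth, elevation, "right_front")
        return 10.0 * np.log10(np.sum(hl ** 2) / np.sum(hr ** 2))


def parametric_harir(direction: tuple[float, float], mic: str,
                     head_radius: float = 0.0875, mic_spacing: float = 0.010,
                     c: float = 343.0, fs: int = 44100) -> np.ndarray:
    """Convenience wrapper: one parametric impulse response.

    ``direction`` is (azimuth, elevation) in degrees, ``mic`` one of
    ``left_front, left_rear, right_front, right_rear``.
    """
    model = ParametricHarir(fs=fs, head_radius=head_radius,
                            mic_spacing=mic_spacing, c=c)
    return model.ir(direction[0], direction[1], mic)


class MeasuredHarir(HarirModel):
    """Measured impulse responses: a dict (azimuth, elevation) -> array of
    shape (4, n_taps) with channels ordered as ``MICS``."""

    def __init__(self, fs: int, irs: dict):
        self.fs = int(fs)
        self._irs = {(round(float(k[0]), 6), round(float(k[1]), 6)): np.asarray(v)
                     for k, v in irs.items()}

    def ir(self, azimuth: float, elevation: float, mic: str) -> np.ndarray:
        key = (round(float(wrap_deg(azimuth)), 6), round(float(elevation), 6))
        if key not in self._irs:
            raise KeyError(f"no measured IR for direction {key}")
        return self._irs[key][MICS.index(mic)]


# ---------------------------------------------------------------------------
# Panning


def _ring_pan_gains(azimuth: float, layout: ArrayLayout) -> np.ndarray:
    """Constant-power pairwise panning gains over all layout channels for
    a horizontal source: the two ring directions bracketing the azimuth
    get gains (cos, sin) of the pair fraction; all others zero."""
    gains = np.zeros(layout.n)
    ring = layout.ring
    ring_az = layout.azimuths[ring]
    # signed arc from each ring direction to the source
    diffs = ang_diff_deg(azimuth, ring_az)
    exact = np.flatnonzero(np.abs(diffs) < 1e-9)
    if exact.size:
        gains[ring[exact[0]]] = 1.0
        return gains
    # nearest direction counterclockwise below and clockwise above
    below = np.where(diffs > 0, diffs, np.inf).argmin()
    above = np.where(diffs < 0, -diffs, np.inf).argmin()
    span = ang_diff_deg(layout.azimuths[ring[above]],
                        layout.azimuths[ring[below]]) % 360.0
    frac = (diffs[below] % 360.0) / span
    gains[ring[below]] = np.cos(frac * np.pi / 2.0)
    gains[ring[above]] = np.sin(frac * np.pi / 2.0)
    return gains


def _nearest_direction(azimuth: float, elevation: float,
                       layout: ArrayLayout) -> int:
    """Nearest layout direction by great-circle distance."""
    az = np.deg2rad(layout.azimuths)
    el = np.deg2rad(layout.elevations)
    v = np.stack([np.cos(az) * np.cos(el), np.sin(az) * np.cos(el),
                  np.sin(el)], axis=-1)
    a, e = np.deg2rad(azimuth), np.deg2rad(elevation)
    u = np.array([np.cos(a) * np.cos(e), np.sin(a) * np.cos(e), np.sin(e)])
    return int(np.argmax(v @ u))


def pan_gains(azimuth: float, elevation: float, layout: ArrayLayout
              ) -> np.ndarray:
    """Panning gains for one source direction: pairwise constant-power on
    the ear-level ring for horizontal sources, nearest-direction snap for
    elevated sources."""
    if abs(elevation) < 1e-9:
        return _ring_pan_gains(azimuth, layout)
    gains = np.zeros(layout.n)
    gains[_nearest_direction(azimuth, elevation, layout)] = 1.0
    return gains


# ---------------------------------------------------------------------------
# Rendering


def render_to_array(spec: SceneSpec, layout: Optional[ArrayLayout] = None,
                    block: int = BLOCK_SIZE) -> dict:
    """Render a scene to per-direction channel signals, one set per role.

    Returns ``{"target": channels, "noise": channels}`` with ``channels``
    of shape (layout.n, n_samples); roles absent from the scene map to
    zeros.  Moving sources are re-panned per block of ``block`` samples
    with linear gain interpolation across each block.  Rendering is linear
    in the source signals, so target and noise channel sets sum to the
    mixture rendering exactly.
    """
    layout = layout or ArrayLayout.default()
    fs = spec.sample_rate
    n = spec.n_samples
    out = {"target": np.zeros((layout.n, n)),
           "noise": np.zeros((layout.n, n))}
    for src in spec.sources:
        sig = np.asarray(src.signal, dtype=float)[:n]
        if sig.size < n:
            sig = np.pad(sig, (0, n - sig.size))
        sig = sig * 10.0 ** (src.gain_db / 20.0)
        if np.isscalar(src.azimuth):
            if not np.isfinite(src.azimuth):
                raise ValueError("source azimuth must be finite")
            g = pan_gains(float(src.azimuth), src.elevation, layout)
            out[src.role] += g[:, None] * sig[None, :]
        else:
            t_blocks = np.arange(0, n, block) / fs
            az_blocks = src.azimuth_at(t_blocks)
            if not np.all(np.isfinite(az_blocks)):
                raise ValueError("source azimuth track contains NaN")
            gains = np.stack([pan_gains(a, src.elevation, layout)
                              for a in az_blocks])  # (n_blocks, n_dirs)
            out[src.role] += _apply_block_gains(sig, gains, block)
    return out


def _apply_block_gains(sig: np.ndarray, gains: np.ndarray, block: int
                       ) -> np.ndarray:
    """Apply per-block panning gains with linear interpolation across each
    block (gain ramps from the previous block's value to the current)."""
    n = sig.size
    n_dirs = gains.shape[1]
    out = np.zeros((n_dirs, n))
    prev = gains[0]
    for k in range(gains.shape[0]):
        i0 = k * block
        i1 = min(i0 + block, n)
        alpha = np.arange(i1 - i0) / block
        g = (1 - alpha)[None, :] * prev[:, None] \
            + alpha[None, :] * gains[k][:, None]
        out[:, i0:i1] = g * sig[i0:i1][None, :]
        prev = gains[k]
    return out


def apply_head_motion(channels: np.ndarray, pose: HeadPose,
                      layout: Optional[ArrayLayout] = None, fs: int = 44100,
                      block: int = BLOCK_SIZE,
                      ring_radius: float = RING_RADIUS) -> np.ndarray:
    """Rotate and shift the virtual listener through the channel signals.

    Per block, every ear-level ring channel (a world-fixed direction at
    ``ring_radius``) is re-panned to its direction as seen from the
    translated listener, minus the head yaw; the level scales with the
    inverse distance ratio.  Elevated channels rotate by yaw with a
    nearest-direction snap within their own ring; the pole is untouched.
    Mixing matrices are linearly cross-faded across each block to avoid
    clicks.

    Raises ``ValueError`` if the pose track ends before the audio does.
    """
    layout = layout or ArrayLayout.default()
    channels = np.asarray(channels, dtype=float)
    n = channels.shape[1]
    duration = n / fs
    if pose.t[-1] < duration - block / fs:
        raise ValueError("pose track shorter than the audio")

    n_blocks = int(np.ceil(n / block))
    t_blocks = np.arange(n_blocks + 1) * block / fs
    yaw_b, pos_b = pose.sample(np.minimum(t_blocks, pose.t[-1]))

    mats = [_motion_matrix(yaw_b[k], pos_b[k], layout, ring_radius)
            for k in range(n_blocks + 1)]

    out = np.zeros_like(channels)
    for k in range(n_blocks):
        i0 = k * block
        i1 = min(i0 + block, n)
        alpha = (np.arange(i1 - i0) / block)[None, :]
        x = channels[:, i0:i1]
        out[:, i0:i1] = (1 - alpha) * (mats[k] @ x) + alpha * (mats[k + 1] @ x)
    return out


def _motion_matrix(yaw: float, pos_xy: np.ndarray, layout: ArrayLayout,
                   ring_radius: float) -> np.ndarray:
    """Channel mixing matrix realizing one head pose."""
    m = np.zeros((layout.n, layout.n))
    ring = set(layout.ring.tolist())
    for i in range(layout.n):
        az_i, el_i = layout.azimuths[i], layout.elevations[i]
        if el_i == 0.0 and i in ring:
            # world-fixed speaker position; listener moved to pos_xy
            sp = ring_radius * np.array([np.cos(np.deg2rad(az_i)),
                                         np.sin(np.deg2rad(az_i))])
            v = sp - pos_xy
            dist = np.hypot(*v)
            az_new = wrap_deg(np.rad2deg(np.arctan2(v[1], v[0])) - yaw)
            gain = ring_radius / max(dist, 1e-3)
            m[:, i] = gain * _ring_pan_gains(az_new, layout)
        elif el_i == 90.0:
            m[i, i] = 1.0
        else:
            j = _nearest_direction(wrap_deg(az_i - yaw), el_i, layout)
            m[j, i] = 1.0
    return m


def to_ha_mics(channels: np.ndarray, layout: Optional[ArrayLayout],
               model: HarirModel, component: str = "mixture"
               ) -> HaMicSignals:
    """Convolve direction channels with HARIRs and sum: 4 mic signals."""
    layout = layout or ArrayLayout.default()
    n = channels.shape[1]
    mics = {}
    for mic in MICS:
        acc = np.zeros(n)
        for i in range(layout.n):
            ch = channels[i]
            if not np.any(ch):
                continue
            h = model.ir(layout.azimuths[i], layout.elevations[i], mic)
            acc += fftconvolve(ch, h)[:n]
        mics[mic] = acc
    return HaMicSignals(**mics, sample_rate=model.fs, component=component)


def plane_wave_to_mics(signal: np.ndarray, azimuth: float, model: HarirModel,
                       elevation: float = 0.0, component: str = "mixture"
                       ) -> HaMicSignals:
    """Anechoic plane wave straight to the 4 hearing-aid microphones."""
    n = len(signal)
    mics = {m: fftconvolve(signal, model.ir(azimuth, elevation, m))[:n]
            for m in MICS}
    return HaMicSignals(**mics, sample_rate=model.fs, component=component)
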