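"""Sensor-stream ingestion and gaze decomposition.

Raw self-motion recordings combine three sensor streams with different
sampling rates: head yaw/translation from motion tracking (200 Hz), torso
yaw from shoulder markers (carried on the head stream's time base), and a
horizontal electrooculogram (EOG, 33 Hz) giving eye-in-head azimuth.  This
module removes the slow EOG drift, resamples everything onto a common
120 Hz timeline, forms the gaze trajectory as head + eye-in-head, and
labels head/eye saccades.

Angle convention: degrees, 0 = straight ahead, positive = leftward
(counterclockwise from above), wrapped to (-180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MotionRecording",
    "GazeDecomposition",
    "SaccadeEvent",
    "correct_eog_drift",
    "fuse",
    "detect_saccades",
    "smoothed_velocity",
    "read_head_stream",
    "read_eye_stream",
    "EYE_VELOCITY_THRESHOLD",
    "HEAD_VELOCITY_THRESHOLD",
    "MIN_SACCADE_AMPLITUDE",
    "SACCADE_MERGE_GAP",
    "VELOCITY_SMOOTHING",
]

# Saccade-detection defaults.  Velocity thresholds follow standard
# oculomotor / head-kinematics ranges: eye saccades exceed ~50 deg/s while
# smooth pursuit stays well below; head reorienting movements are slower.
EYE_VELOCITY_THRESHOLD = 50.0  # deg/s
HEAD_VELOCITY_THRESHOLD = 20.0  # deg/s
MIN_SACCADE_AMPLITUDE = 3.0  # deg
SACCADE_MERGE_GAP = 0.05  # s
VELOCITY_SMOOTHING = 0.05  # s, moving-average length before differentiation


@dataclass
class MotionRecording:
    """Raw multi-sensor trajectory bundle for one participant x environment.

    ``t_head`` carries head yaw (deg), head translation (m) and torso yaw
    (deg) at ``f_head`` (default 200 Hz); ``t_eog`` carries the calibrated,
    degree-scaled EOG at ``f_eog`` (default 33 Hz).
    """

    t_head: np.ndarray
    head_yaw: np.ndarray
    head_translation_xy: np.ndarray  # shape (n, 2), metres
    torso_yaw: np.ndarray
    t_eog: np.ndarray
    eog_raw: np.ndarray
    participant_id: str = "anonymous"
    environment_id: str = "unknown"
    group: str = "NH_young"

    def __post_init__(self) -> None:
        self.t_head = np.asarray(self.t_head, dtype=float)
        self.head_yaw = np.asarray(self.head_yaw, dtype=float)
        self.head_translation_xy = np.atleast_2d(
            np.asarray(self.head_translation_xy, dtype=float)
        )
        self.torso_yaw = np.asarray(self.torso_yaw, dtype=float)
        self.t_eog = np.asarray(self.t_eog, dtype=float)
        self.eog_raw = np.asarray(self.eog_raw, dtype=float)
        for name, t in (("head", self.t_head), ("eog", self.t_eog)):
            if t.size == 0:
                raise ValueError(f"empty {name} time axis")
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"{name} time axis not strictly increasing")
        for name, s in (
            ("head_yaw", self.head_yaw),
            ("torso_yaw", self.torso_yaw),
            ("eog_raw", self.eog_raw),
        ):
            if not np.all(np.isfinite(s)):
                raise ValueError(f"non-finite values in {name}")

    @property
    def duration(self) -> float:
        return float(min(self.t_head[-1], self.t_eog[-1])
                     - max(self.t_head[0], self.t_eog[0]))


@dataclass
class SaccadeEvent:
    """A rapid reorienting movement of the eye, head, or gaze."""

    onset: float  # s
    offset: float  # s
    amplitude: float  # deg, >= 0
    effector: str  # "eye" | "head" | "gaze"

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ValueError("saccade offset must exceed onset")
        if self.amplitude < 0:
            raise ValueError("saccade amplitude must be non-negative")


@dataclass
class GazeDecomposition:
    """Fused head/eye/gaze/torso azimuth series on one 120 Hz time axis.

    The defining identity ``gaze = head_yaw + eye_in_head`` holds exactly,
    sample-wise; relative-to-torso series are plain differences.
    """

    t: np.ndarray
    head_yaw: np.ndarray
    eye_in_head: np.ndarray
    torso_yaw: np.ndarray
    saccade_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    saccades: dict = field(default_factory=dict)  # effector -> [SaccadeEvent]

    def __post_init__(self) -> None:
        n = len(self.t)
        if self.saccade_mask is None:
            self.saccade_mask = np.zeros(n, dtype=bool)
        for name in ("head_yaw", "eye_in_head", "torso_yaw", "saccade_mask"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from time axis")

    @property
    def gaze(self) -> np.ndarray:
        return self.head_yaw + self.eye_in_head

    @property
    def head_re_torso(self) -> np.ndarray:
        return self.head_yaw - self.torso_yaw

    @property
    def gaze_re_torso(self) -> np.ndarray:
        return self.gaze - self.torso_yaw

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


def _linear_extrapolation_pad(x: np.ndarray, pad: int) -> np.ndarray:
    """Pad both ends by straight-line extrapolation of the first/last
    ``pad`` samples (least-squares line through them)."""
    idx = np.arange(pad, dtype=float)
    # leading end: line fitted to x[:pad], evaluated at -pad..-1
    b0, a0 = np.polyfit(idx, x[:pad], 1)
    lead = a0 + b0 * np.arange(-pad, 0, dtype=float)
    # trailing end: line fitted to x[-pad:], evaluated beyond the end
    b1, a1 = np.polyfit(idx, x[-pad:], 1)
    trail = a1 + b1 * np.arange(pad, 2 * pad, dtype=float)
    return np.concatenate([lead, x, trail])


def correct_eog_drift(eog_raw: np.ndarray, window: int = 500) -> np.ndarray:
    """Remove slow electrode drift from a calibrated EOG series.

    The drift estimate is the series padded at both ends by linear
    extrapolation (of the first/last ``window // 2`` samples) and smoothed
    with a centered moving average of ``window`` samples; the estimate is
    subtracted from the input.  Padding makes the centered average defined
    over the full support.

    Parameters
    ----------
    eog_raw : array of shape (n,)
        Calibrated eye-in-head azimuth, degrees. ``n`` must exceed ``window``.
    window : int
        Moving-average length in samples (default 500; about 15 s at the
        33 Hz EOG rate).

    Returns
    -------
    array of shape (n,)
        Drift-corrected series (zero-mean apart from genuine eye movement).
    """
    x = np.asarray(eog_raw, dtype=float)
    if x.ndim != 1:
        raise ValueError("eog_raw must be one-dimensional")
    if window < 2:
        raise ValueError("window must be at least 2 samples")
    if x.size <= window:
        raise ValueError(
            f"series length {x.size} must exceed the smoothing window {window}"
        )
    pad = window // 2
    padded = _linear_extrapolation_pad(x, pad)
    kernel = np.full(window, 1.0 / window)
    smoothed = np.convolve(padded, kernel, mode="same")
    drift = smoothed[pad:pad + x.size]
    return x - drift


def _interp(t_new: np.ndarray, t_old: np.ndarray, x: np.ndarray) -> np.ndarray:
    return np.interp(t_new, t_old, x)


def fuse(
    rec: MotionRecording,
    f_fused: float = 120.0,
    detect: bool = True,
    eye_v_thresh: float = EYE_VELOCITY_THRESHOLD,
    head_v_thresh: float = HEAD_VELOCITY_THRESHOLD,
    min_amp: float = MIN_SACCADE_AMPLITUDE,
    merge_gap: float = SACCADE_MERGE_GAP,
    drift_window: int = 500,
    correct_drift: bool = True,
) -> GazeDecomposition:
    """Fuse head and (drift-corrected) eye streams into a gaze decomposition.

    All streams are linearly interpolated onto a common time axis at
    ``f_fused`` (default 120 Hz) spanning the overlap of the head and EOG
    supports; gaze = head + eye-in-head.  When ``detect`` is true, eye and
    head saccades are detected on the fused series and their union fills
    ``saccade_mask`` (gaze saccades are detected on the gaze series and
    stored under ``"gaze"``).

    Raises
    ------
    ValueError
        If the streams do not overlap in time, or a stream is empty.
    """
    eog = rec.eog_raw
    if correct_drift:
        # shrink the window for recordings shorter than the default 500
        # samples so short fixtures remain processable
        w = drift_window if eog.size > drift_window else max(2, eog.size - 1)
        eog = correct_eog_drift(eog, window=w)
    t0 = max(rec.t_head[0], rec.t_eog[0])
    t1 = min(rec.t_head[-1], rec.t_eog[-1])
    if t1 <= t0:
        raise ValueError("head and EOG streams do not overlap in time")
    n = int(np.floor((t1 - t0) * f_fused)) + 1
    if n < 2:
        raise ValueError("overlapping support shorter than two fused samples")
    t = t0 + np.arange(n) / f_fused

    head = _interp(t, rec.t_head, rec.head_yaw)
    torso = _interp(t, rec.t_head, rec.torso_yaw)
    eye = _interp(t, rec.t_eog, eog)

    g = GazeDecomposition(t=t, head_yaw=head, eye_in_head=eye, torso_yaw=torso)
    if detect:
        eye_sacc = detect_saccades(eye, f_fused, eye_v_thresh, min_amp, merge_gap,
                                   effector="eye")
        head_sacc = detect_saccades(head, f_fused, head_v_thresh, min_amp,
                                    merge_gap, effector="head")
        gaze_sacc = detect_saccades(g.gaze, f_fused, eye_v_thresh, min_amp,
                                    merge_gap, effector="gaze")
        mask = np.zeros(n, dtype=bool)
        for ev in eye_sacc + head_sacc:
            i0 = int(np.searchsorted(t, t[0] + ev.onset))
            i1 = int(np.searchsorted(t, t[0] + ev.offset, side="right"))
            mask[i0:i1] = True
        g.saccade_mask = mask
        g.saccades = {"eye": eye_sacc, "head": head_sacc, "gaze": gaze_sacc}
    return g


def smoothed_velocity(series: np.ndarray, fs: float,
                      smoothing: float = VELOCITY_SMOOTHING) -> np.ndarray:
    """Angular velocity (deg/s) by central differences after a short
    moving-average smooth (default 50 ms)."""
    x = np.asarray(series, dtype=float)
    if x.size < 3:
        return np.zeros_like(x)
    k = max(1, int(round(smoothing * fs)))
    if k > 1:
        kernel = np.full(k, 1.0 / k)
        # reflect-pad so the smooth is defined at the edges
        xp = np.concatenate([x[k - 1:0:-1], x, x[-2:-k - 1:-1]])
        x = np.convolve(xp, kernel, mode="same")[k - 1:k - 1 + series.size]
    return np.gradient(x) * fs


def detect_saccades(
    series: np.ndarray,
    fs: float,
    v_thresh: float,
    min_amp: float = MIN_SACCADE_AMPLITUDE,
    merge_gap: float = SACCADE_MERGE_GAP,
    effector: str = "gaze",
) -> list[SaccadeEvent]:
    """Detect saccades on a uniformly sampled azimuth series.

    Contiguous runs where the smoothed absolute angular velocity exceeds
    ``v_thresh`` become candidate events; events separated by less than
    ``merge_gap`` seconds merge; events whose amplitude (|end - start|
    of the series over the event) is below ``min_amp`` are dropped.
    Onset/offset times are relative to the start of the series.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 3:
        return []
    v = smoothed_velocity(x, fs)
    above = np.abs(v) > v_thresh
    if not above.any():
        return []
    # contiguous runs of True
    idx = np.flatnonzero(above)
    runs: list[list[int]] = []
    run_start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i == prev + 1:
            prev = i
            continue
        runs.append([run_start, prev])
        run_start = i
        prev = i
    runs.append([run_start, prev])
    # merge runs closer than merge_gap
    gap = merge_gap * fs
    merged: list[list[int]] = [runs[0]]
    for r in runs[1:]:
        if r[0] - merged[-1][1] <= gap:
            merged[-1][1] = r[1]
        else:
            merged.append(r)
    events: list[SaccadeEvent] = []
    for i0, i1 in merged:
        amp = abs(x[min(i1 + 1, x.size - 1)] - x[max(i0 - 1, 0)])
        if amp < min_amp:
            continue
        events.append(
            SaccadeEvent(
                onset=i0 / fs,
                offset=(i1 + 1) / fs,
                amplitude=float(amp),
                effector=effector,
            )
        )
    return events


def read_head_stream(path) -> pd.DataFrame:
    """Read a head-stream trajectory file.

    Delimited text with a header row and columns
    ``t, head_yaw, head_x, head_y, torso_yaw`` (s, deg, m, m, deg).
    """
    df = pd.read_csv(path)
    required = ["t", "head_yaw", "head_x", "head_y", "torso_yaw"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"head stream missing columns: {missing}")
    if np.any(np.diff(df["t"].to_numpy()) <= 0):
        raise ValueError("head stream time not strictly increasing")
    return df


def read_eye_stream(path) -> pd.DataFrame:
    """Read an eye-stream trajectory file (columns ``t, eog``; s, deg)."""
    df = pd.read_csv(path)
    missing = [c for c in ("t", "eog") if c not in df.columns]
    if missing:
        raise ValueError(f"eye stream missing columns: {missing}")
    if np.any(np.diff(df["t"].to_numpy()) <= 0):
        raise ValueError("eye stream time not strictly increasing")
    return df


def recording_from_files(head_path, eye_path, **meta) -> MotionRecording:
    """Build a MotionRecording from head- and eye-stream files."""
    h = read_head_stream(head_path)
    e = read_eye_stream(eye_path)
    return MotionRecording(
        t_head=h["t"].to_numpy(),
        head_yaw=h["head_yaw"].to_numpy(),
        head_translation_xy=h[["head_x", "head_y"]].to_numpy(),
        torso_yaw=h["torso_yaw"].to_numpy(),
        t_eog=e["t"].to_numpy(),
        eog_raw=e["eog"].to_numpy(),
        **meta,
    )
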