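"""Per-participant, per-environment movement measures.

Given a fused gaze decomposition and (optionally) the azimuth track of the
active target speaker, this module computes the scalar measures used to
compare listener groups:

* GazeStd / HeadStd — standard deviation of the gaze / head yaw trajectory.
* GazeSpeedMean / HeadSpeedMean — mean absolute angular velocity.
* NGazeJumps — gaze-saccade count normalized by duration (events/minute).
* HeadGazeRatio — fraction of the torso-relative gaze angle carried by the
  head during fixations (1 = all head, 0 = all eyes), with three per-sample
  exclusion rules (see :func:`head_gaze_ratio`).
* TargetGazeRMS / TargetHeadRMS — RMS error between gaze / head direction
  and the target direction (undefined for environments with no target).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._angles import ang_diff_deg
from .trajectories import GazeDecomposition, SaccadeEvent, smoothed_velocity

__all__ = [
    "TargetTrack",
    "MovementMeasures",
    "basic_measures",
    "head_gaze_ratio",
    "target_rms",
    "compute_all",
    "measures_table",
]


@dataclass
class TargetTrack:
    """Piecewise-constant azimuth of the active speaker over time.

    ``defined`` is False for environments with no target (e.g. passively
    waiting at an intersection), in which case target-relative measures
    are undefined.
    """

    t: np.ndarray
    target_azimuth: np.ndarray
    defined: bool = True

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.target_azimuth = np.asarray(self.target_azimuth, dtype=float)
        if self.defined and not np.all(np.isfinite(self.target_azimuth)):
            raise ValueError("target azimuth must be finite where defined")

    def at(self, t: np.ndarray) -> np.ndarray:
        """Sample the track at arbitrary times (piecewise-constant hold)."""
        idx = np.clip(np.searchsorted(self.t, t, side="right") - 1, 0, None)
        return self.target_azimuth[idx]


@dataclass
class MovementMeasures:
    GazeStd: float  # deg
    HeadStd: float  # deg
    GazeSpeedMean: float  # deg/s
    HeadSpeedMean: float  # deg/s
    NGazeJumps: float  # events per minute
    HeadGazeRatio: Optional[float]  # in [0, 1], None if no sample survives
    TargetGazeRMS: Optional[float]  # deg, None if no target defined
    TargetHeadRMS: Optional[float]  # deg
    excluded_fraction: float  # fraction of samples excluded in HeadGazeRatio

    def as_dict(self) -> dict:
        return asdict(self)


def basic_measures(g: GazeDecomposition,
                   gaze_saccades: Sequence[SaccadeEvent] | None = None) -> dict:
    """Trajectory spread, speed and gaze-jump-rate measures.

    Speeds use the same velocity estimator as saccade detection (central
    differences after a 50 ms moving-average smooth) over the full series.
    NGazeJumps counts detected gaze saccades per minute of recording.
    """
    if len(g.t) < 2:
        raise ValueError("need at least two samples for movement measures")
    fs = g.fs
    if gaze_saccades is None:
        gaze_saccades = g.saccades.get("gaze", [])
    duration_min = g.duration / 60.0
    return {
        "GazeStd": float(np.std(g.gaze, ddof=1)),
        "HeadStd": float(np.std(g.head_yaw, ddof=1)),
        "GazeSpeedMean": float(np.mean(np.abs(smoothed_velocity(g.gaze, fs)))),
        "HeadSpeedMean": float(np.mean(np.abs(smoothed_velocity(g.head_yaw, fs)))),
        "NGazeJumps": len(gaze_saccades) / duration_min if duration_min > 0
        else 0.0,
    }


def head_gaze_ratio(g: GazeDecomposition, min_gaze: float = 10.0
                    ) -> tuple[Optional[float], float]:
    """Mean per-sample |head|/|gaze| ratio (torso-relative) during fixations.

    Three per-sample exclusion rules apply before averaging:

    (a) samples during a head or eye saccade are excluded — the measure
        targets the static orientation, and head and eyes move with
        different timing and speed;
    (b) samples where the head angle exceeds the gaze angle in magnitude,
        or has opposite sign, are excluded (the ratio has no clear meaning
        there); a head angle of exactly 0 counts as same-sign, since a
        ratio of 0 is meaningful all-eye behavior;
    (c) samples with |gaze| below ``min_gaze`` (default 10 deg) are
        excluded to avoid division by near-zero and sensor-noise-dominated
        ratios.

    Returns ``(ratio, excluded_fraction)``; ratio is None when no sample
    survives (a legitimate outcome, not an error).  Rule (b) forces the
    ratio into [0, 1].
    """
    head = g.head_re_torso
    gaze = g.gaze_re_torso
    n = head.size
    if n == 0:
        return None, 1.0

    keep = ~g.saccade_mask
    same_sign = (np.sign(head) == np.sign(gaze)) | (head == 0.0)
    keep &= (np.abs(head) <= np.abs(gaze)) & same_sign
    keep &= np.abs(gaze) >= min_gaze

    excluded = 1.0 - keep.sum() / n
    if not keep.any():
        return None, excluded
    ratio = float(np.mean(np.abs(head[keep]) / np.abs(gaze[keep])))
    return ratio, excluded


def target_rms(series: np.ndarray, t: np.ndarray, target: TargetTrack
               ) -> Optional[float]:
    """RMS of the wrapped angular error between a trajectory and the target.

    Returns None when the environment defines no target.  Differences use
    the shortest signed arc, so a simultaneous +-360 deg wrap of both
    series and target leaves the result unchanged.
    """
    if not target.defined:
        return None
    err = ang_diff_deg(np.asarray(series, dtype=float), target.at(t))
    return float(np.sqrt(np.mean(err ** 2)))


def compute_all(g: GazeDecomposition, target: Optional[TargetTrack] = None,
                min_gaze: float = 10.0) -> MovementMeasures:
    """All movement measures for one recording."""
    basics = basic_measures(g)
    ratio, excl = head_gaze_ratio(g, min_gaze=min_gaze)
    if target is not None and target.defined:
        tg = target_rms(g.gaze, g.t, target)
        th = target_rms(g.head_yaw, g.t, target)
    else:
        tg = th = None
    return MovementMeasures(
        **basics,
        HeadGazeRatio=ratio,
        TargetGazeRMS=tg,
        TargetHeadRMS=th,
        excluded_fraction=excl,
    )


def measures_table(rows: Sequence[tuple[str, str, str, MovementMeasures]]
                   ) -> pd.DataFrame:
    """Tidy long-format table of measures.

    ``rows`` holds (participant_id, group, environment_id, measures)
    tuples; the output has one row per measure with a ``defined`` flag
    (False where a measure could not be calculated).  NGazeJumps is in
    events per minute.
    """
    records = []
    for pid, group, env, m in rows:
        for name, value in m.as_dict().items():
            if name == "excluded_fraction":
                continue
            records.append({
                "participant_id": pid,
                "group": group,
                "environment_id": env,
                "measure": name,
                "value": np.nan if value is None else value,
                "defined": value is not None,
            })
    return pd.DataFrame.from_records(records)
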