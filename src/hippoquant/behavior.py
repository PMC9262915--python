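"""Locomotion kinematics and novel-object-location (NOL) scoring.

Positions come from video tracking at a fixed frame rate (15 frames/s in the
experiments this package targets).  Speed is the frame-to-frame displacement
times the frame rate, passed through a 3-frame median filter to suppress
tracking jitter; instantaneous acceleration is the centered difference of
speed times the frame rate (one-sided at the endpoints).

Object exploration is scored by frame membership in the 2 cm perimetral zone
around each object — the annulus between the object footprint and footprint
+ zone width — and the discrimination index is
(displaced − familiar) / (displaced + familiar) exploration time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import medfilt

__all__ = [
    "Track",
    "NolConfig",
    "kinematics",
    "exploration_times",
    "discrimination_index",
]


@dataclass
class Track:
    """Time-stamped 2-D positions with derived kinematics.

    ``speed_mps`` / ``accel_mps2`` are filled by :func:`kinematics`.
    """

    t_s: np.ndarray
    x_m: np.ndarray
    y_m: np.ndarray
    frame_rate_hz: float = 15.0
    speed_mps: np.ndarray | None = None
    accel_mps2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=np.float64)
        self.x_m = np.asarray(self.x_m, dtype=np.float64)
        self.y_m = np.asarray(self.y_m, dtype=np.float64)
        if not (self.t_s.shape == self.x_m.shape == self.y_m.shape):
            raise ValueError("t, x, y must have equal length")
        if self.t_s.size >= 2:
            dt = np.diff(self.t_s)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if not np.allclose(dt, 1.0 / self.frame_rate_hz, rtol=1e-6, atol=1e-9):
                raise ValueError("timestamps must be spaced at 1/frame_rate")

    @property
    def n_frames(self) -> int:
        return self.t_s.size

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    def to_dataframe(self) -> pd.DataFrame:
        d = {"frame": np.arange(self.n_frames), "t_s": self.t_s,
             "x_m": self.x_m, "y_m": self.y_m}
        if self.speed_mps is not None:
            d["speed_mps"] = self.speed_mps
        if self.accel_mps2 is not None:
            d["accel_mps2"] = self.accel_mps2
        return pd.DataFrame(d)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, frame_rate_hz: float = 15.0) -> "Track":
        return cls(df["t_s"].to_numpy(), df["x_m"].to_numpy(),
                   df["y_m"].to_numpy(), frame_rate_hz)

    def total_distance_m(self) -> float:
        return float(np.sum(np.hypot(np.diff(self.x_m), np.diff(self.y_m))))


@dataclass(frozen=True)
class NolConfig:
    """Arena and object geometry for the novel-object-location task.

    The exploration zone is the 2 cm-wide annulus around each object's
    footprint; the default arena is the 0.35 x 0.24 m open field.
    """

    object_centers_m: tuple[tuple[float, float], tuple[float, float]]
    object_radius_m: float = 0.02
    zone_width_m: float = 0.02
    arena_size_m: tuple[float, float] = (0.35, 0.24)

    def __post_init__(self) -> None:
        w, h = self.arena_size_m
        outer = self.object_radius_m + self.zone_width_m
        for cx, cy in self.object_centers_m:
            if not (0 <= cx <= w and 0 <= cy <= h):
                raise ValueError(f"object center ({cx}, {cy}) outside arena")
        (x1, y1), (x2, y2) = self.object_centers_m
        if np.hypot(x2 - x1, y2 - y1) < 2 * outer:
            raise ValueError("object zones overlap")


def kinematics(track: Track) -> Track:
    """Fill speed and acceleration in place and return the track.

    speed = |frame-to-frame displacement| x frame rate, median-filtered over
    3 frames; acceleration = centered difference of speed x frame rate with
    one-sided differences at the ends.
    """
    n = track.n_frames
    if n < 3:
        raise ValueError("kinematics needs at least 3 frames")
    fr = track.frame_rate_hz
    step = np.hypot(np.diff(track.x_m), np.diff(track.y_m)) * fr
    speed = np.empty(n)
    speed[:-1] = step
    speed[-1] = step[-1]
    speed = medfilt(speed, 3)
    accel = np.empty(n)
    accel[1:-1] = (speed[2:] - speed[:-2]) * fr / 2.0
    accel[0] = (speed[1] - speed[0]) * fr
    accel[-1] = (speed[-1] - speed[-2]) * fr
    track.speed_mps = speed
    track.accel_mps2 = accel
    return track


def zone_membership(track: Track, cfg: NolConfig) -> np.ndarray:
    """Boolean (n_objects, n_frames) matrix of annulus membership per frame.

    A frame belongs to object ``o`` iff the head position lies in the
    half-open annulus [radius, radius + zone_width) around ``o``'s center.
    """
    inner, outer = cfg.object_radius_m, cfg.object_radius_m + cfg.zone_width_m
    out = np.zeros((len(cfg.object_centers_m), track.n_frames), dtype=bool)
    for k, (cx, cy) in enumerate(cfg.object_centers_m):
        d = np.hypot(track.x_m - cx, track.y_m - cy)
        out[k] = (d >= inner) & (d < outer)
    return out


def exploration_times(track: Track, cfg: NolConfig) -> pd.DataFrame:
    """Per-object exploration time and entry count.

    time = in-zone frame count / frame rate; an entry is the first frame of
    each maximal in-zone run.
    """
    member = zone_membership(track, cfg)
    rows = []
    for k in range(member.shape[0]):
        m = member[k]
        entries = int(np.count_nonzero(np.diff(np.r_[False, m].astype(np.int8)) == 1))
        rows.append({"object": k,
                     "time_s": float(np.count_nonzero(m)) / track.frame_rate_hz,
                     "entries": entries})
    return pd.DataFrame(rows)


def discrimination_index(t_displaced_s: float, t_familiar_s: float) -> float:
    """(displaced − familiar) / (displaced + familiar) exploration.

    Positive values indicate preference for the displaced object.  Returns
    NaN (undefined) when total exploration is zero, so the session can be
    excluded from group tables.
    """
    if t_displaced_s < 0 or t_familiar_s < 0:
        raise ValueError("exploration times must be >= 0")
    total = t_displaced_s + t_familiar_s
    if total == 0:
        return float("nan")
    return (t_displaced_s - t_familiar_s) / total
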