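"""Fiber-photometry processing: isosbestic ΔF/F, mobility segmentation,
transition-triggered averages, acceleration-response curves and the
per-animal acceleration modulation index.

The calcium-dependent channel (465 nm excitation) and the isosbestic control
channel (405 nm) share bleaching and motion artifacts but only the 465 nm
channel carries calcium dynamics.  ΔF/F is computed by least-squares affine
mapping of the 405 channel onto the 465 channel over the whole session and
taking the fractional residual, which removes the shared slow trend and
artifacts and is zero-mean by construction.

Acceleration coupling is summarized per animal by fitting a quadratic to the
instantaneous (acceleration, z-scored ΔF/F) cloud and reporting the fitted
difference between the response at a reference acceleration (95th percentile
of |a|) and at its negative — a scalar that is zero for an acceleration-blind
signal and grows with the accel-vs-decel asymmetry of the response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior import Track, kinematics
from .core import IntervalSet, UniformSignal

__all__ = [
    "DffParams",
    "MobilityParams",
    "ModulationResult",
    "isosbestic_dff",
    "segment_mobility",
    "transition_triggered_average",
    "acceleration_response_curve",
    "modulation_index",
]


@dataclass(frozen=True)
class DffParams:
    fit_degree: int = 1
    output_percent: bool = True

    def __post_init__(self) -> None:
        if self.fit_degree != 1:
            raise ValueError("only an affine (degree-1) 405->465 fit is supported")


@dataclass(frozen=True)
class MobilityParams:
    """Speed-threshold mobility segmentation."""

    speed_threshold_mps: float = 0.02
    min_bout_s: float = 1.0
    merge_gap_s: float = 0.5

    def __post_init__(self) -> None:
        if not self.speed_threshold_mps > 0:
            raise ValueError("speed threshold must be > 0")
        if self.min_bout_s < 0 or self.merge_gap_s < 0:
            raise ValueError("durations must be >= 0")


@dataclass(frozen=True)
class ModulationResult:
    """Quadratic acceleration-coupling fit and its scalar index."""

    a2: float
    a1: float
    a0: float
    a_ref: float          # m/s^2, 95th percentile of |acceleration|
    index: float          # yhat(+a_ref) - yhat(-a_ref) = 2 * a1 * a_ref
    n_points: int


def isosbestic_dff(f465: UniformSignal, f405: UniformSignal,
                   params: DffParams | None = None) -> UniformSignal:
    """Isosbestic-corrected ΔF/F (percent by default).

    fit = least-squares affine map of the 405 channel onto the 465 channel
    over the whole session; ΔF/F(t) = (f465(t) − fit(f405)(t)) / fit(f405)(t),
    in percent by default.  Mean ΔF/F is ~0 by construction of the fit.
    """
    params = params or DffParams()
    if f465.rate_hz != f405.rate_hz or f465.n != f405.n:
        raise ValueError("channels must share rate and span")
    x, y = f405.values, f465.values
    if np.std(x) == 0:
        raise ValueError("isosbestic channel has zero variance; cannot fit")
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    if np.any(fitted <= 0):
        raise ValueError("fitted control crosses zero; check channel scaling")
    dff = (y - fitted) / fitted
    scale = 100.0 if params.output_percent else 1.0
    return f465.with_values(scale * dff, units="%" if params.output_percent else "dimensionless")


def segment_mobility(track: Track, params: MobilityParams | None = None
                     ) -> tuple[IntervalSet, IntervalSet]:
    """(mobility, immobility) partition of the track span by speed threshold.

    Frames with speed above threshold are mobile; mobile runs shorter than
    ``min_bout_s`` are dropped, then gaps shorter than ``merge_gap_s`` are
    merged.  Immobility is the complement within the track span.
    """
    params = params or MobilityParams()
    if track.n_frames == 0:
        raise ValueError("empty track")
    if track.duration_s < params.min_bout_s:
        raise ValueError("track shorter than min_bout_s")
    if track.speed_mps is None:
        kinematics(track)
    fr = track.frame_rate_hz
    mask = track.speed_mps > params.speed_threshold_mps
    raw = IntervalSet.from_mask(mask, fr, t0_s=track.t_s[0])
    kept = [(s, e) for s, e in raw if e - s >= params.min_bout_s]
    merged: list[list[float]] = []
    for s, e in kept:
        if merged and s - merged[-1][1] < params.merge_gap_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    span = (track.t_s[0], track.t_s[0] + track.duration_s)
    mobility = IntervalSet([tuple(p) for p in merged])
    return mobility, mobility.complement(span)


def transitions(mobility: IntervalSet, kind: str = "onset") -> np.ndarray:
    """Transition times: bout starts (``onset``) or bout ends (``offset``)."""
    if kind == "onset":
        return mobility.starts.copy()
    if kind == "offset":
        return mobility.ends.copy()
    raise ValueError("kind must be 'onset' or 'offset'")


def transition_triggered_average(signal: UniformSignal, transition_times,
                                 window_s: tuple[float, float] = (2.0, 2.0)) -> dict:
    """Event-triggered average of the session-z-scored signal.

    Snippets ``[-pre, +post]`` around each transition are aligned at t = 0
    and averaged pointwise; transitions whose window leaves the recorded span
    are dropped and counted in ``n_dropped``.  A zero-variance signal is
    flagged and averaged un-scaled.
    """
    pre, post = window_s
    sd = float(np.std(signal.values))
    flagged = sd == 0
    z = signal.values - np.mean(signal.values)
    if not flagged:
        z = z / sd
    rate = signal.rate_hz
    n_pre = int(round(pre * rate))
    n_post = int(round(post * rate))
    snippets = []
    dropped = 0
    for t in np.atleast_1d(np.asarray(transition_times, dtype=float)):
        i = int(round((t - signal.t0_s) * rate))
        if i - n_pre < 0 or i + n_post + 1 > z.size:
            dropped += 1
            continue
        snippets.append(z[i - n_pre:i + n_post + 1])
    if not snippets:
        raise ValueError("no transition has a full window inside the signal span")
    arr = np.asarray(snippets)
    n = arr.shape[0]
    return {
        "t_s": (np.arange(-n_pre, n_post + 1)) / rate,
        "mean": arr.mean(axis=0),
        "sem": arr.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(arr.shape[1]),
        "n": n,
        "n_dropped": dropped,
        "zero_variance": flagged,
    }


def align_dff_to_track(dff: UniformSignal, track: Track) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous (acceleration, z-ΔF/F) pairs on the tracking timebase.

    ΔF/F is z-scored over the session and downsampled to the track's frame
    times by a windowed mean (one frame period per window); frames whose
    window leaves the recording are dropped.
    """
    if track.accel_mps2 is None:
        kinematics(track)
    sd = float(np.std(dff.values))
    if sd == 0:
        raise ValueError("ΔF/F has zero variance")
    z = (dff.values - np.mean(dff.values)) / sd
    half = 0.5 / track.frame_rate_hz
    accel, zds = [], []
    for t, a in zip(track.t_s, track.accel_mps2):
        i0 = int(np.ceil((t - half - dff.t0_s) * dff.rate_hz))
        i1 = int(np.floor((t + half - dff.t0_s) * dff.rate_hz)) + 1
        if i0 < 0 or i1 > z.size or i1 <= i0:
            continue
        accel.append(a)
        zds.append(float(np.mean(z[i0:i1])))
    if not accel:
        raise ValueError("ΔF/F and track do not overlap in time")
    return np.asarray(accel), np.asarray(zds)


def acceleration_response_curve(dff: UniformSignal, track: Track,
                                n_bins: int = 10) -> pd.DataFrame:
    """Binned acceleration-response curve of z-scored ΔF/F.

    Instantaneous pairs are split into ``n_bins`` equal-count bins separately
    for negative and positive acceleration; per-bin center, mean, sem and
    count are returned.
    """
    a, y = align_dff_to_track(dff, track)
    if a.size < 10 * n_bins:
        raise ValueError(
            f"need at least {10 * n_bins} instantaneous pairs, got {a.size}")
    rows = []
    for sign, sel in (("decel", a < 0), ("accel", a > 0)):
        av, yv = a[sel], y[sel]
        if av.size == 0:
            continue
        k = min(n_bins, av.size)
        edges = np.quantile(av, np.linspace(0, 1, k + 1))
        idx = np.clip(np.searchsorted(edges, av, side="right") - 1, 0, k - 1)
        for b in range(k):
            m = idx == b
            nb = int(np.count_nonzero(m))
            if nb == 0:
                continue
            rows.append({
                "side": sign,
                "accel_mps2": float(np.mean(av[m])),
                "mean_z_dff": float(np.mean(yv[m])),
                "sem_z_dff": float(np.std(yv[m], ddof=1) / np.sqrt(nb)) if nb > 1 else 0.0,
                "n": nb,
            })
    return pd.DataFrame(rows).sort_values("accel_mps2").reset_index(drop=True)


def modulation_index(accel: np.ndarray, z_dff: np.ndarray) -> ModulationResult:
    """Quadratic acceleration-coupling fit and scalar modulation index.

    Least squares ``yhat = a2 x^2 + a1 x + a0`` on the instantaneous pairs;
    ``a_ref`` is the 95th percentile of |acceleration| and
    ``index = yhat(+a_ref) − yhat(−a_ref)`` (equal to ``2 a1 a_ref``).
    """
    x = np.asarray(accel, dtype=float)
    y = np.asarray(z_dff, dtype=float)
    if x.size != y.size:
        raise ValueError("accel and z_dff must have equal length")
    if x.size < 10:
        raise ValueError("need at least 10 instantaneous pairs")
    if not (np.any(x > 0) and np.any(x < 0)):
        raise ValueError("acceleration must span positive and negative values")
    a2, a1, a0 = np.polyfit(x, y, 2)
    a_ref = float(np.percentile(np.abs(x), 95))
    index = float(2.0 * a1 * a_ref)
    return ModulationResult(a2=float(a2), a1=float(a1), a0=float(a0),
                            a_ref=a_ref, index=index, n_points=x.size)
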