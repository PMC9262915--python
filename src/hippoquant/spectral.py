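"""Band-power estimation and theta-segment selection for hippocampal LFP.

Spectra are Welch averages of Hamming-windowed periodograms at a fixed
frequency resolution (default 0.5 Hz, i.e. 2 s windows) with 50 % overlap,
one-sided and Parseval-consistent (the integral of the density approximates
the signal variance).  Mains contamination (50 Hz and harmonics) is removed
by notching the affected bins and interpolating log-power across the notch,
which respects the 1/f background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .core import IntervalSet, UniformSignal

__all__ = [
    "SpectralSummary",
    "ThetaSegmentParams",
    "power_spectrum",
    "interpolate_line_noise",
    "band_power",
    "theta_ratio_8_4",
    "find_theta_segments",
]


@dataclass(frozen=True)
class SpectralSummary:
    """One-sided power spectral density on a uniform frequency grid."""

    freqs_hz: np.ndarray          # ascending, spacing = resolution_hz
    power: np.ndarray             # units^2 / Hz, >= 0
    resolution_hz: float
    n_windows: int
    window: str = "hamming"

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs_hz, dtype=np.float64)
        p = np.asarray(self.power, dtype=np.float64)
        if f.shape != p.shape:
            raise ValueError("freqs and power must have equal length")
        if np.any(p < 0):
            raise ValueError("power must be non-negative")
        if f.size > 1 and not np.allclose(np.diff(f), self.resolution_hz):
            raise ValueError("frequency grid spacing must equal resolution_hz")
        object.__setattr__(self, "freqs_hz", f)
        object.__setattr__(self, "power", p)


@dataclass(frozen=True)
class ThetaSegmentParams:
    """Sliding-window criteria for continuous-theta segments.

    A window counts as theta when its 4–10 Hz power exceeds
    ``ratio_threshold`` times its 1–4 Hz power; runs of qualifying windows
    shorter than ``min_segment_s`` are dropped.
    """

    window_s: float = 2.0
    step_s: float = 1.0
    theta_band: tuple[float, float] = (4.0, 10.0)
    reference_band: tuple[float, float] = (1.0, 4.0)
    ratio_threshold: float = 2.0
    min_segment_s: float = 3.0

    def __post_init__(self) -> None:
        if not self.ratio_threshold > 0:
            raise ValueError("ratio_threshold must be > 0")
        lo1, hi1 = self.reference_band
        lo2, hi2 = self.theta_band
        if not (lo1 < hi1 <= lo2 < hi2):
            raise ValueError("reference band must lie below a disjoint theta band")


def power_spectrum(samples: np.ndarray, rate_hz: float,
                   resolution_hz: float = 0.5) -> SpectralSummary:
    """Welch PSD with Hamming windows of length ``1/resolution_hz`` seconds.

    50 %-overlapping windows, no detrending, one-sided density scaling.
    """
    x = np.asarray(samples, dtype=np.float64)
    nperseg = int(round(rate_hz / resolution_hz))
    if x.size < nperseg:
        raise ValueError(
            f"need at least one full window ({nperseg} samples at "
            f"{resolution_hz} Hz resolution), got {x.size}")
    noverlap = nperseg // 2
    freqs, pxx = sps.welch(x, fs=rate_hz, window="hamming", nperseg=nperseg,
                           noverlap=noverlap, detrend=False, scaling="density")
    n_windows = 1 + (x.size - nperseg) // (nperseg - noverlap)
    return SpectralSummary(freqs, pxx, resolution_hz=float(freqs[1] - freqs[0]),
                           n_windows=n_windows)


def interpolate_line_noise(spec: SpectralSummary, line_hz: float = 50.0,
                           n_harmonics: int = 3, halfwidth_hz: float = 2.0) -> SpectralSummary:
    """Replace mains bins by log-power interpolation across each notch.

    Bins within ``±halfwidth_hz`` of ``k*line_hz`` (k = 1..n_harmonics) are
    replaced by linear interpolation of log-power between the nearest
    untouched flanking bins; every other bin is returned bit-identical.
    """
    if not (halfwidth_hz < line_hz / 2):
        raise ValueError("halfwidth must be below line_hz/2")
    f, p = spec.freqs_hz, spec.power.copy()
    fmax = f[-1]
    notch = np.zeros(f.size, dtype=bool)
    for k in range(1, n_harmonics + 1):
        fk = k * line_hz
        if fk - halfwidth_hz > fmax:
            continue
        notch |= np.abs(f - fk) <= halfwidth_hz
    if not notch.any():
        return spec
    starts = np.flatnonzero(np.r_[notch[0], np.diff(notch.astype(np.int8)) == 1])
    stops = np.flatnonzero(np.r_[np.diff(notch.astype(np.int8)) == -1, notch[-1]]) + 1
    for i0, i1 in zip(starts, stops):
        lo, hi = i0 - 1, i1
        if lo < 0 or hi >= f.size:
            raise ValueError(
                f"notch band {f[i0]:.1f}-{f[i1 - 1]:.1f} Hz reaches the spectrum "
                "edge; no flanking bins to interpolate from")
        idx = np.arange(i0, i1)
        if p[lo] > 0 and p[hi] > 0:
            logv = np.interp(idx, [lo, hi], np.log([p[lo], p[hi]]))
            p[idx] = np.exp(logv)
        else:  # zero flank: fall back to linear interpolation
            p[idx] = np.interp(idx, [lo, hi], [p[lo], p[hi]])
    return replace(spec, power=p)


def band_power(spec: SpectralSummary, lo_hz: float, hi_hz: float) -> float:
    """Integrated density over the half-open band ``[lo_hz, hi_hz)``."""
    if not (lo_hz < hi_hz):
        raise ValueError("need lo < hi")
    f = spec.freqs_hz
    if lo_hz < f[0] or hi_hz > f[-1] + spec.resolution_hz:
        raise ValueError(
            f"band ({lo_hz}, {hi_hz}) outside spectrum range ({f[0]}, {f[-1]})")
    sel = (f >= lo_hz) & (f < hi_hz)
    return math.fsum(spec.power[sel]) * spec.resolution_hz


def theta_ratio_8_4(spec: SpectralSummary, band_halfwidth_hz: float = 0.0) -> float:
    """Density at the 8.0 Hz bin divided by density at the 4.0 Hz bin.

    ``band_halfwidth_hz > 0`` averages density over ``±halfwidth`` around
    each frequency instead of single bins.  Returns NaN when the 4 Hz
    denominator is zero (flagged undefined).
    """
    f = spec.freqs_hz

    def _at(f0: float) -> float:
        if band_halfwidth_hz > 0:
            sel = np.abs(f - f0) <= band_halfwidth_hz
            if not sel.any():
                raise ValueError(f"no bins within {band_halfwidth_hz} Hz of {f0} Hz")
            return float(np.mean(spec.power[sel]))
        i = int(np.argmin(np.abs(f - f0)))
        if abs(f[i] - f0) > 1e-6:
            raise ValueError(f"spectrum has no bin at {f0} Hz (nearest {f[i]} Hz)")
        return float(spec.power[i])

    num, den = _at(8.0), _at(4.0)
    if den == 0:
        return float("nan")
    return num / den


def find_theta_segments(signal: UniformSignal,
                        params: ThetaSegmentParams | None = None) -> IntervalSet:
    """Continuous-theta segments by a sliding theta/delta power-ratio criterion.

    Each ``window_s`` window (stepped by ``step_s``) is marked when the
    theta-band power exceeds ``ratio_threshold`` times the reference-band
    power; maximal unions of consecutive marked windows at least
    ``min_segment_s`` long are returned.
    """
    params = params or ThetaSegmentParams()
    win = int(round(params.window_s * signal.rate_hz))
    step = int(round(params.step_s * signal.rate_hz))
    if signal.n < win:
        raise ValueError(f"signal span shorter than window_s={params.window_s}")
    window = sps.get_window("hamming", win)
    scale = 1.0 / (signal.rate_hz * np.sum(window ** 2))
    freqs = np.fft.rfftfreq(win, d=signal.dt)
    th = (freqs >= params.theta_band[0]) & (freqs < params.theta_band[1])
    ref = (freqs >= params.reference_band[0]) & (freqs < params.reference_band[1])

    marked: list[bool] = []
    starts_idx: list[int] = []
    for i0 in range(0, signal.n - win + 1, step):
        seg = signal.values[i0:i0 + win] * window
        pxx = scale * np.abs(np.fft.rfft(seg)) ** 2
        p_th, p_ref = float(np.sum(pxx[th])), float(np.sum(pxx[ref]))
        marked.append(p_ref > 0 and p_th / p_ref > params.ratio_threshold
                      or (p_ref == 0 and p_th > 0))
        starts_idx.append(i0)

    out: list[tuple[float, float]] = []
    cur_start: float | None = None
    cur_end = 0.0
    for ok, i0 in zip(marked, starts_idx):
        t0 = signal.t0_s + i0 / signal.rate_hz
        t1 = t0 + params.window_s
        if ok:
            if cur_start is None:
                cur_start = t0
            elif t0 > cur_end:  # non-contiguous windows
                if cur_end - cur_start >= params.min_segment_s:
                    out.append((cur_start, cur_end))
                cur_start = t0
            cur_end = t1
        else:
            if cur_start is not None and cur_end - cur_start >= params.min_segment_s:
                out.append((cur_start, cur_end))
            cur_start = None
    if cur_start is not None and cur_end - cur_start >= params.min_segment_s:
        out.append((cur_start, cur_end))
    return IntervalSet(out)
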