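"""Sharp-wave-ripple (SWR) detection from the pyramidal-layer LFP.

The detection chain is the classic envelope-threshold scheme: band-pass the
LFP in the ripple band (70–250 Hz), rectify, smooth with a Gaussian kernel to
obtain an envelope, express the envelope in standard-deviation units of its
distribution during immobility, and take maximal supra-threshold runs as
candidate events.  Per-event power is reported in those baseline-SD units
(mean and maximum of the standardized envelope over the event), which makes
every power measure invariant to rescaling the raw voltage.

A multi-session mode pools the immobility envelopes of several sessions and
detects in each session with the shared baseline, so that rate comparisons
across sessions cannot be driven by per-session threshold differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d

from .core import EventTable, IntervalSet, UniformSignal, restrict

__all__ = [
    "RippleParams",
    "BaselineStats",
    "ripple_bandpass_kernel",
    "ripple_envelope",
    "baseline_stats",
    "detect_swr",
    "swr_rate",
    "detect_swr_common_threshold",
]


@dataclass(frozen=True)
class RippleParams:
    """Ripple-band detection parameters.

    band 70–250 Hz and the >3 SD threshold follow standard CA1 ripple
    criteria; the envelope kernel SD (8 ms — a little over one ripple cycle,
    enough to integrate over the ripple-band noise correlation time so the
    envelope within a burst does not fragment), the 1 SD boundary, the
    20–250 ms duration gate and the 15 ms merge gap are phenomenological
    defaults exposed here.
    """

    band_lo_hz: float = 70.0
    band_hi_hz: float = 250.0
    envelope_gauss_sd_ms: float = 8.0
    threshold_sd: float = 3.0
    boundary_sd: float = 1.0
    min_dur_ms: float = 20.0
    max_dur_ms: float = 250.0
    merge_gap_ms: float = 15.0

    def __post_init__(self) -> None:
        if not (0 < self.band_lo_hz < self.band_hi_hz):
            raise ValueError("need 0 < band_lo < band_hi")
        if not (self.threshold_sd > self.boundary_sd > 0):
            raise ValueError("need threshold_sd > boundary_sd > 0")
        if not (self.min_dur_ms < self.max_dur_ms):
            raise ValueError("need min_dur_ms < max_dur_ms")


@dataclass(frozen=True)
class BaselineStats:
    """Envelope mean/SD over immobility, the detector's reference frame."""

    mu: float
    sd: float
    source_intervals: IntervalSet
    n_samples: int

    def __post_init__(self) -> None:
        if not (self.sd > 0):
            raise ValueError("baseline sd must be > 0")


def ripple_bandpass_kernel(rate_hz: float, lo_hz: float, hi_hz: float) -> np.ndarray:
    """Symmetric (zero-phase) Hamming-window FIR band-pass kernel.

    The tap count is set from the low band edge so the stopband (>= 40 dB
    down) is reached by 0.8*lo and 1.2*hi at any sampling rate.
    """
    transition_hz = 0.15 * lo_hz
    numtaps = int(np.ceil(3.3 * rate_hz / transition_hz))
    numtaps += 1 - numtaps % 2  # odd length -> exactly linear phase
    return sps.firwin(numtaps, [lo_hz, hi_hz], pass_zero=False,
                      window="hamming", fs=rate_hz)


def ripple_envelope(signal: UniformSignal, params: RippleParams | None = None) -> UniformSignal:
    """Gaussian-smoothed rectified ripple-band signal.

    Zero-phase band-pass (symmetric FIR), absolute value, then Gaussian
    smoothing with SD ``envelope_gauss_sd_ms``.  Same rate and span as the
    input.
    """
    params = params or RippleParams()
    if signal.rate_hz < 2 * params.band_hi_hz:
        raise ValueError(
            f"sampling rate {signal.rate_hz} Hz below Nyquist requirement "
            f"{2 * params.band_hi_hz} Hz for band_hi {params.band_hi_hz} Hz")
    kernel = ripple_bandpass_kernel(signal.rate_hz, params.band_lo_hz, params.band_hi_hz)
    filt = sps.fftconvolve(signal.values, kernel, mode="same")
    sd_samples = params.envelope_gauss_sd_ms * 1e-3 * signal.rate_hz
    env = gaussian_filter1d(np.abs(filt), sd_samples, mode="nearest")
    return signal.with_values(env, units="dimensionless")


def baseline_stats(envelope: UniformSignal, immobility: IntervalSet,
                   min_duration_s: float = 10.0) -> BaselineStats:
    """Envelope mean/SD restricted to immobility ("non-movement") periods."""
    dur = immobility.intersect_span((envelope.t0_s, envelope.t_end_s)).duration()
    if dur < min_duration_s:
        raise ValueError(
            f"immobility duration {dur:.2f} s below required minimum "
            f"{min_duration_s} s for baseline estimation")
    samples = restrict(envelope, immobility)
    return BaselineStats(mu=float(np.mean(samples)), sd=float(np.std(samples)),
                         source_intervals=immobility, n_samples=samples.size)


def _runs_above(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start (inclusive) / stop (exclusive) indices of True runs."""
    if mask.size == 0 or not mask.any():
        return np.empty(0, int), np.empty(0, int)
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(np.r_[mask[0], d == 1])
    stops = np.flatnonzero(np.r_[d == -1, mask[-1]]) + 1
    return starts, stops


def detect_swr(envelope: UniformSignal, stats: BaselineStats,
               params: RippleParams | None = None) -> EventTable:
    """Threshold the standardized envelope and gate candidates by duration.

    Candidates are maximal runs with ``z > threshold_sd``.  Runs separated by
    less than ``merge_gap_ms`` are merged when the envelope stays above the
    ``boundary_sd`` level throughout the gap (noise can fragment the
    supra-threshold core of one ripple, but between fragments the envelope
    remains elevated, unlike between independent noise spikes).  The minimum
    duration gate applies to the merged supra-threshold core — a genuine
    ripple stays above threshold for tens of ms, while the boundary extension
    would stretch any brief noise spike past the gate.  Surviving candidates
    are extended outward to where ``z < boundary_sd`` (event onset/offset),
    overlapping extensions are merged, and events longer than ``max_dur_ms``
    are discarded.  Per event: ``mean_power_sd`` / ``max_power_sd`` are
    mean / max z over ``[onset, offset)`` and ``peak_s`` the argmax time.
    """
    params = params or RippleParams()
    z = (envelope.values - stats.mu) / stats.sd
    rate = envelope.rate_hz
    starts, stops = _runs_above(z > params.threshold_sd)
    if starts.size == 0:
        return EventTable.empty()

    # bridge fragmented cores: gap < merge_gap and z > boundary throughout
    gap_samples = params.merge_gap_ms * 1e-3 * rate
    cores: list[list[int]] = [[int(starts[0]), int(stops[0])]]
    for i0, i1 in zip(starts[1:], stops[1:]):
        gap = slice(cores[-1][1], i0)
        if i0 - cores[-1][1] < gap_samples and np.all(z[gap] > params.boundary_sd):
            cores[-1][1] = int(i1)
        else:
            cores.append([int(i0), int(i1)])
    core_min = params.min_dur_ms * 1e-3 * rate
    kept = [(a, b) for a, b in cores if b - a >= core_min]
    if not kept:
        return EventTable.empty()
    starts = np.array([a for a, _ in kept])
    stops = np.array([b for _, b in kept])

    # extend each candidate outward to the boundary crossing
    below = z < params.boundary_sd
    below_idx = np.flatnonzero(below)
    onsets = np.empty(starts.size, dtype=int)
    offsets = np.empty(starts.size, dtype=int)
    for k, (i0, i1) in enumerate(zip(starts, stops)):
        j = np.searchsorted(below_idx, i0) - 1
        onsets[k] = below_idx[j] + 1 if j >= 0 else 0
        j = np.searchsorted(below_idx, i1 - 1)
        offsets[k] = below_idx[j] if j < below_idx.size else z.size
    # overlapping extensions and events separated by < merge_gap collapse
    gap_samples = params.merge_gap_ms * 1e-3 * rate
    merged: list[list[int]] = []
    for on, off in zip(onsets, offsets):
        if merged and on - merged[-1][1] < gap_samples:
            merged[-1][1] = max(merged[-1][1], off)
        else:
            merged.append([on, off])

    rows = {"onset_s": [], "peak_s": [], "offset_s": [],
            "amplitude": [], "mean_power_sd": [], "max_power_sd": [],
            "duration_ms": []}
    max_len = params.max_dur_ms * 1e-3 * rate
    for on, off in merged:
        if off - on > max_len:
            continue
        seg = z[on:off]
        ipk = on + int(np.argmax(seg))
        rows["onset_s"].append(envelope.t0_s + on / rate)
        rows["offset_s"].append(envelope.t0_s + off / rate)
        rows["peak_s"].append(envelope.t0_s + ipk / rate)
        rows["amplitude"].append(float(z[ipk]))
        rows["mean_power_sd"].append(float(np.mean(seg)))
        rows["max_power_sd"].append(float(np.max(seg)))
        rows["duration_ms"].append((off - on) / rate * 1e3)
    return EventTable(**rows)


def swr_rate(events: EventTable, immobility: IntervalSet,
             denominator: str = "immobility") -> float:
    """Event rate: peaks inside immobility per second of immobility.

    ``denominator="span"`` divides by the full extent of the interval set's
    span instead (first start to last end).
    """
    if len(immobility) == 0 or immobility.duration() <= 0:
        raise ValueError("immobility duration must be > 0")
    n_in = int(np.count_nonzero(immobility.contains(events["peak_s"]))) if len(events) else 0
    if denominator == "immobility":
        dur = immobility.duration()
    elif denominator == "span":
        dur = float(immobility.ends[-1] - immobility.starts[0])
    else:
        raise ValueError("denominator must be 'immobility' or 'span'")
    return n_in / dur


def detect_swr_common_threshold(
    sessions: list[tuple[UniformSignal, IntervalSet]],
    params: RippleParams | None = None,
) -> tuple[list[EventTable], BaselineStats]:
    """Detect per session with a baseline pooled over all sessions.

    The baseline mean/SD is computed on the concatenation of every session's
    immobility-restricted envelope, then :func:`detect_swr` runs per session
    with those shared stats.  All sessions must share the sampling rate.
    """
    params = params or RippleParams()
    if len(sessions) < 1:
        raise ValueError("need at least one session")
    rates = {env.rate_hz for env, _ in sessions}
    if len(rates) != 1:
        raise ValueError(f"heterogeneous sampling rates across sessions: {sorted(rates)}")
    pooled = np.concatenate([restrict(env, imm) for env, imm in sessions])
    if pooled.size < 2:
        raise ValueError("pooled immobility envelope is empty")
    all_ivs = IntervalSet()  # provenance: stats come from several clocks
    stats = BaselineStats(mu=float(np.mean(pooled)), sd=float(np.std(pooled)),
                          source_intervals=all_ivs, n_samples=pooled.size)
    tables = [detect_swr(env, stats, params) for env, _ in sessions]
    return tables, stats
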