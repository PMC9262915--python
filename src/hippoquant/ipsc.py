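"""Spontaneous IPSC detection from voltage-clamp current traces.

Events are found with a threshold trigger on a differentiated copy of the
trace: the first difference (scaled to pA/ms, optionally boxcar-smoothed)
must stay above threshold for a minimum trigger duration.  Amplitude is the
polarity-corrected excursion of the trace from the median of a pre-onset
baseline window to the extremum inside a short post-onset search window.
Recordings at 0 mV yield outward (positive) GABAergic currents, hence the
default polarity of +1; inward events use polarity -1.

The trigger threshold and duration are exposed rather than fixed — in
practice they are adjusted per cell to reject slow membrane fluctuations and
instrument noise — and the parameters used are carried in the summary output.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .core import EventTable, UniformSignal

__all__ = ["IpscDetectParams", "detect_ipsc_events", "summarize_ipsc"]


@dataclass(frozen=True)
class IpscDetectParams:
    """Threshold-trigger parameters for the differentiated trace."""

    derivative_threshold: float = 10.0   # pA/ms
    trigger_duration_ms: float = 0.5
    smoothing_ms: float = 2.0            # boxcar on the derivative; 0 = none
    peak_window_ms: float = 10.0
    peak_smoothing_ms: float = 1.0       # boxcar before peak measurement;
    baseline_window_ms: float = 5.0      # without it the extremum rides the
    refractory_ms: float = 2.0           # noise maximum and biases amplitude up
    rearm_level: float = 0.0             # pA/ms the derivative must drop below
    polarity: int = +1                   # before the trigger re-arms

    def __post_init__(self) -> None:
        if not self.derivative_threshold > 0:
            raise ValueError("derivative_threshold must be > 0")
        for name in ("trigger_duration_ms", "smoothing_ms", "peak_window_ms",
                     "peak_smoothing_ms", "baseline_window_ms", "refractory_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.polarity not in (-1, +1):
            raise ValueError("polarity must be +1 or -1")


def detect_ipsc_events(signal: UniformSignal,
                       params: IpscDetectParams | None = None) -> EventTable:
    """Threshold-triggered event detection on the differentiated trace.

    Returns an :class:`EventTable` with onset, peak, offset (end of the peak
    search window), amplitude in pA, and the peak derivative of each event.
    """
    params = params or IpscDetectParams()
    rate = signal.rate_hz
    if rate < 1000:
        raise ValueError("IPSC detection expects a sampling rate >= 1 kHz")
    if params.trigger_duration_ms > 0 and params.trigger_duration_ms * 1e-3 * rate < 2:
        raise ValueError(
            f"trigger_duration {params.trigger_duration_ms} ms spans fewer than "
            f"2 samples at {rate} Hz; increase the duration or the rate")
    trig_n = max(1, int(round(params.trigger_duration_ms * 1e-3 * rate)))

    x = params.polarity * signal.values
    xs = x
    if params.peak_smoothing_ms > 0:
        wp = max(1, int(round(params.peak_smoothing_ms * 1e-3 * rate)))
        xs = uniform_filter1d(x, wp, mode="nearest")
    deriv = np.diff(x) * rate * 1e-3  # pA per ms
    if params.smoothing_ms > 0:
        w = max(1, int(round(params.smoothing_ms * 1e-3 * rate)))
        deriv = uniform_filter1d(deriv, w, mode="nearest")

    above = deriv > params.derivative_threshold
    # run-length encode supra-threshold stretches
    d = np.diff(above.astype(np.int8))
    run_starts = np.flatnonzero(np.r_[above[0] if above.size else False, d == 1])
    run_stops = np.flatnonzero(np.r_[d == -1, above[-1] if above.size else False]) + 1

    peak_n = max(1, int(round(params.peak_window_ms * 1e-3 * rate)))
    base_n = max(1, int(round(params.baseline_window_ms * 1e-3 * rate)))
    refr_n = params.refractory_ms * 1e-3 * rate

    # Schmitt-trigger re-arm: after an event, the derivative must fall below
    # rearm_level before a new trigger may fire.  This makes the event count
    # monotone in the threshold (every higher-threshold event nests inside a
    # lower-threshold run) and stops one rising phase from double-triggering.
    rearm_idx = np.flatnonzero(deriv < params.rearm_level)

    rows = {"onset_s": [], "peak_s": [], "offset_s": [], "amplitude": [],
            "peak_derivative_pa_per_ms": []}
    last_onset = -np.inf
    for i0, i1 in zip(run_starts, run_stops):
        if i1 - i0 < trig_n:
            continue
        if i0 - last_onset < refr_n:
            continue
        if np.isfinite(last_onset):
            j = np.searchsorted(rearm_idx, i0)
            if j == 0 or rearm_idx[j - 1] <= last_onset:
                continue  # derivative never re-armed since the last event
        last_onset = i0
        pk_sl = slice(i0, min(i0 + peak_n, x.size))
        ipk = i0 + int(np.argmax(xs[pk_sl]))
        base = xs[max(0, i0 - base_n):i0]
        baseline = float(np.median(base)) if base.size else float(xs[i0])
        amp = float(xs[ipk] - baseline)
        rows["onset_s"].append(signal.t0_s + i0 / rate)
        rows["peak_s"].append(signal.t0_s + ipk / rate)
        rows["offset_s"].append(signal.t0_s + min(i0 + peak_n, x.size - 1) / rate)
        rows["amplitude"].append(amp)
        rows["peak_derivative_pa_per_ms"].append(float(np.max(deriv[i0:i1])))
    return EventTable(**rows)


def summarize_ipsc(events: EventTable, recording_duration_s: float,
                   params: IpscDetectParams | None = None) -> dict:
    """Per-cell summary: event frequency, mean amplitude, count.

    ``mean_amplitude_pA`` is NaN when no events were detected (undefined,
    not zero).  Detection parameters, when given, are echoed for provenance.
    """
    if not recording_duration_s > 0:
        raise ValueError("recording duration must be > 0")
    n = len(events)
    out = {
        "frequency_hz": n / recording_duration_s,
        "mean_amplitude_pA": float(np.mean(events["amplitude"])) if n else float("nan"),
        "n_events": n,
    }
    if params is not None:
        out["params"] = asdict(params)
    return out
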