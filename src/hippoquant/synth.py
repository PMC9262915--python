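"""Seeded synthetic-data generators with ground truth for every pipeline stage.

Each generator is a pure function of (config, seed): the same config and seed
reproduce the output bit-for-bit, and the returned ground truth is sufficient
to score the corresponding detector (recall/precision/parameter recovery)
without re-reading the raw signal.

What the generators emulate
---------------------------
* ``simulate_lfp`` — CA1 pyramidal-layer LFP: 1/f background noise, theta
  (8 Hz) plus band-limited gamma (30–90 Hz) present only during mobility, and
  Gaussian-enveloped 150 Hz ripple bursts arriving as a Poisson process during
  immobility.  Ripple amplitude is specified in analysis-envelope SD units
  (the detector's own reference frame) and realized by a calibration loop
  against :mod:`hippoquant.swr`'s envelope definition.
* ``simulate_ipsc_trace`` — voltage-clamp current at 0 mV: slow drift,
  band-limited Gaussian noise, and Poisson-arriving outward biexponential
  events with log-normal amplitudes.
* ``simulate_photometry`` — two-channel fiber photometry: a bout-structured
  speed profile drives GCaMP-kernel-filtered activity on the 465 nm channel;
  both channels share the bleaching trend and the motion artifact.
* ``simulate_nol_track`` — open-field random walk at 15 frames/s with an
  optional dwell bias near the displaced object, plus exact per-object zone
  times under the same annulus membership rule the scorer uses.
* ``simulate_stain_image`` — confocal-like channel stack: somata ("PV"),
  graded somatic staining ("arom"), perineuronal rings ("WFA") on a stated
  fraction of cells, and ~1 µm mRNA dots at programmed densities inside and
  outside cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .behavior import NolConfig, Track
from .core import EventTable, IntervalSet, UniformSignal
from .histology import AnnotatedImage
from . import swr as _swr

__all__ = [
    "LfpSimConfig",
    "IpscSimConfig",
    "PhotometrySimConfig",
    "StainSimConfig",
    "alternating_schedule",
    "simulate_lfp",
    "simulate_ipsc_trace",
    "simulate_photometry",
    "photometry_channels",
    "simulate_nol_track",
    "simulate_stain_image",
]


# ---------------------------------------------------------------------------
# shared noise helpers


def _shaped_noise(n: int, shape: np.ndarray, std: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with the given rFFT amplitude shape and *expected* SD.

    Normalization uses the analytic expected variance rather than the realized
    one, so independent realizations are draws from the identical process
    (per-realization rescaling would anti-correlate band powers).
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white) * shape
    w = np.full(shape.size, 2.0)
    w[0] = 1.0
    if n % 2 == 0:
        w[-1] = 1.0
    exp_var = float(np.sum(w * shape ** 2)) / n
    x = np.fft.irfft(spec, n=n)
    return x * (std / np.sqrt(exp_var)) if exp_var > 0 else x


def one_over_f_noise(n: int, rate_hz: float, exponent: float, std: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Spectrally shaped Gaussian noise with power ∝ f^-exponent, expected SD."""
    f = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    return _shaped_noise(n, shape, std, rng)


def band_noise(n: int, rate_hz: float, lo_hz: float, hi_hz: float, rms: float,
               rng: np.random.Generator) -> np.ndarray:
    """Band-limited Gaussian noise with the requested expected RMS."""
    f = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    shape = ((f >= lo_hz) & (f < hi_hz)).astype(np.float64)
    return _shaped_noise(n, shape, rms, rng)


def _poisson_times(rate_hz: float, lo: float, hi: float,
                   rng: np.random.Generator) -> np.ndarray:
    if hi <= lo or rate_hz <= 0:
        return np.empty(0)
    n = rng.poisson(rate_hz * (hi - lo))
    return np.sort(rng.uniform(lo, hi, size=n))


def _thin_refractory(times: np.ndarray, refractory_s: float) -> np.ndarray:
    kept: list[float] = []
    for t in times:
        if not kept or t - kept[-1] >= refractory_s:
            kept.append(t)
    return np.asarray(kept)


def alternating_schedule(duration_s: float, bout_s: float = 20.0,
                         start_mobile: bool = True) -> IntervalSet:
    """Alternating mobility bouts of fixed length covering half the session."""
    edges = np.arange(0.0, duration_s, bout_s)
    ivs = []
    mobile = start_mobile
    for s in edges:
        e = min(s + bout_s, duration_s)
        if mobile and e > s:
            ivs.append((s, e))
        mobile = not mobile
    return IntervalSet(ivs)


# ---------------------------------------------------------------------------
# LFP with ripples


@dataclass(frozen=True)
class LfpSimConfig:
    """Synthetic CA1 LFP: 1/f noise + movement-gated theta/gamma + ripples.

    ``ripple_amp_sd`` is the target ripple-envelope peak in units of the
    baseline (immobility) envelope SD, realized by calibrating the injected
    raw amplitude against the analysis envelope.  ``ripple_dur_ms`` is the SD
    of the Gaussian ripple envelope.  Amplitudes are in mV: 0.1 mV 1/f
    background, 0.3 mV theta and 0.03 mV RMS gamma are typical of mouse CA1
    stratum pyramidale.
    """

    duration_s: float = 600.0
    rate_hz: float = 20000.0
    ripple_rate_hz: float = 0.3
    ripple_freq_hz: float = 150.0
    ripple_dur_ms: float = 20.0
    ripple_amp_sd: float = 6.0
    theta_freq_hz: float = 8.0
    theta_amp_mv: float = 0.3
    theta_4hz_frac: float = 0.5   # 4 Hz component co-scaling with theta
    gamma_band_hz: tuple[float, float] = (30.0, 90.0)
    gamma_rms_mv: float = 0.03
    noise_spectral_exponent: float = 1.0
    noise_std_mv: float = 0.1
    mobility_schedule: IntervalSet | None = None
    ripple_refractory_s: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.rate_hz <= 0:
            raise ValueError("duration and rate must be > 0")
        if self.ripple_rate_hz < 0:
            raise ValueError("ripple_rate_hz must be >= 0")
        if self.ripple_amp_sd <= 0:
            raise ValueError("ripple_amp_sd must be > 0")


def _ripple_kernel(cfg: LfpSimConfig, rate: float) -> np.ndarray:
    """Unit-amplitude Gaussian-enveloped ripple-frequency burst (±4 SD)."""
    sigma = cfg.ripple_dur_ms * 1e-3
    half = int(round(4 * sigma * rate))
    tt = np.arange(-half, half + 1) / rate
    return np.exp(-tt ** 2 / (2 * sigma ** 2)) * np.sin(2 * np.pi * cfg.ripple_freq_hz * tt)


def simulate_lfp(cfg: LfpSimConfig,
                 ripple_params: "_swr.RippleParams | None" = None
                 ) -> tuple[UniformSignal, EventTable, IntervalSet]:
    """Synthesize an LFP with ground-truth ripples and a mobility schedule.

    Returns ``(signal, ground_truth_events, mobility)``.  Ground-truth rows
    carry onset/peak/offset (±3 envelope SD around the burst center), the
    programmed amplitude in baseline-SD units, and the injected raw amplitude
    in mV.
    """
    rng = np.random.default_rng(cfg.seed)
    params = ripple_params or _swr.RippleParams()
    rate = cfg.rate_hz
    n = int(round(cfg.duration_s * rate))
    t = np.arange(n) / rate

    mobility = (cfg.mobility_schedule if cfg.mobility_schedule is not None
                else alternating_schedule(cfg.duration_s))
    immobility = mobility.complement((0.0, cfg.duration_s))
    if cfg.ripple_rate_hz > 0 and immobility.duration() == 0:
        raise ValueError("ripple_rate_hz > 0 requires some immobility in the schedule")

    # movement-gated oscillations on a 1/f background
    noise = one_over_f_noise(n, rate, cfg.noise_spectral_exponent, cfg.noise_std_mv, rng)
    mask = mobility.contains(t).astype(np.float64)
    mask = gaussian_filter1d(mask, 0.05 * rate)  # 50 ms edge smoothing
    # theta with a fixed-fraction 4 Hz component: the 8/4 power ratio is a
    # waveform-shape property and stays put when theta amplitude scales
    theta = cfg.theta_amp_mv * (
        np.sin(2 * np.pi * cfg.theta_freq_hz * t + rng.uniform(0, 2 * np.pi))
        + cfg.theta_4hz_frac * np.sin(2 * np.pi * cfg.theta_freq_hz / 2 * t
                                      + rng.uniform(0, 2 * np.pi)))
    gamma = band_noise(n, rate, *cfg.gamma_band_hz, cfg.gamma_rms_mv, rng)
    background = noise + (theta + gamma) * mask

    # ripple times: Poisson within immobility, kept clear of interval edges;
    # the draw rate is dead-time corrected (r = lam/(1+lam*tau)) so that the
    # post-refractory ground-truth rate matches ripple_rate_hz
    sigma = cfg.ripple_dur_ms * 1e-3
    margin = 4 * sigma + 0.01
    lam = cfg.ripple_rate_hz / max(
        1.0 - cfg.ripple_rate_hz * cfg.ripple_refractory_s, 0.5)
    times: list[np.ndarray] = []
    for s, e in immobility:
        times.append(_poisson_times(lam, s + margin, e - margin, rng))
    all_times = _thin_refractory(np.sort(np.concatenate(times)) if times else np.empty(0),
                                 cfg.ripple_refractory_s)

    if all_times.size == 0:
        return (UniformSignal(background, rate, units="mV"), EventTable.empty(), mobility)

    # calibrate the raw ripple amplitude against the analysis envelope
    kernel = _ripple_kernel(cfg, rate)
    bg_sig = UniformSignal(background, rate, units="mV")
    env_bg = _swr.ripple_envelope(bg_sig, params)
    stats = _swr.baseline_stats(env_bg, immobility)

    pad = int(round(1.0 * rate))
    probe = np.zeros(2 * pad + kernel.size)
    probe[pad:pad + kernel.size] = kernel
    gain = float(np.max(_swr.ripple_envelope(
        UniformSignal(probe, rate, units="mV"), params).values))

    centers = np.round(all_times * rate).astype(int)
    half = kernel.size // 2

    def _inject(amps_mv: np.ndarray) -> np.ndarray:
        sig = background.copy()
        for c, a in zip(centers, amps_mv):
            sig[c - half:c + half + 1] += a * kernel
        return sig

    def _peak_z(sig: np.ndarray) -> np.ndarray:
        # measured in the detector's own frame: baseline stats are re-estimated
        # from the injected signal (single-pass, events included), exactly as
        # the analysis will do
        env = _swr.ripple_envelope(UniformSignal(sig, rate, units="mV"), params)
        st = _swr.baseline_stats(env, immobility)
        z = (env.values - st.mu) / st.sd
        w = int(round(sigma * rate))
        return np.array([np.max(z[max(c - w, 0):c + w + 1]) for c in centers])

    # per-event calibration: the target amplitude is defined as the analysis
    # envelope peak in baseline-SD units, so each event's raw amplitude is
    # refined against the envelope it actually produces on its own noise
    target = cfg.ripple_amp_sd
    amps0 = np.full(centers.size, (stats.mu + target * stats.sd) / gain)
    z0 = _peak_z(_inject(amps0))
    amps1 = amps0 * np.clip(target / z0, 0.5, 2.0)
    z1 = _peak_z(_inject(amps1))
    # secant step on the (amp -> envelope peak z) response of each event
    slope = (z1 - z0) / np.where(amps1 != amps0, amps1 - amps0, 1.0)
    ok = slope > 1e-9
    amps = np.where(ok, amps1 + (target - z1) / np.where(ok, slope, 1.0), amps1)
    amps = np.clip(amps, 0.25 * amps0, 4.0 * amps0)
    values = _inject(amps)

    gt = EventTable(
        onset_s=all_times - 3 * sigma,
        peak_s=all_times,
        offset_s=all_times + 3 * sigma,
        amplitude=np.full(all_times.size, cfg.ripple_amp_sd),
        raw_amp_mv=amps,
    )
    return UniformSignal(values, rate, units="mV"), gt, mobility


# ---------------------------------------------------------------------------
# voltage-clamp IPSC traces


@dataclass(frozen=True)
class IpscSimConfig:
    """Synthetic sIPSC recording at 0 mV (outward events, pA).

    Noise is band-limited Gaussian (the acquisition chain low-pass filters
    before digitizing); ``noise_bandwidth_hz`` sets the equivalent cutoff.
    Event amplitudes are log-normal with mean ``amp_mean_pA`` and coefficient
    of variation ``amp_cv``.
    """

    duration_s: float = 120.0
    rate_hz: float = 20000.0
    event_rate_hz: float = 5.0
    rise_ms: float = 0.5
    decay_ms: float = 10.0
    amp_mean_pA: float = 50.0
    amp_cv: float = 0.3
    noise_sd_pA: float = 5.0
    noise_bandwidth_hz: float = 2000.0
    drift_amp_pA: float = 5.0
    polarity: int = +1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.rise_ms < self.decay_ms):
            raise ValueError("need 0 < rise_ms < decay_ms")
        if self.event_rate_hz < 0:
            raise ValueError("event_rate_hz must be >= 0")
        if self.polarity not in (-1, +1):
            raise ValueError("polarity must be +1 or -1")


def ipsc_kernel(rise_ms: float, decay_ms: float, rate_hz: float) -> np.ndarray:
    """Unit-peak biexponential synaptic kernel exp(-t/τd) − exp(-t/τr)."""
    tr, td = rise_ms * 1e-3, decay_ms * 1e-3
    t = np.arange(0, int(round(8 * td * rate_hz))) / rate_hz
    k = np.exp(-t / td) - np.exp(-t / tr)
    return k / np.max(k)


def simulate_ipsc_trace(cfg: IpscSimConfig) -> tuple[UniformSignal, EventTable]:
    """Drift + band-limited noise + Poisson biexponential events.

    Ground truth holds the true onset, the true peak time (onset + kernel
    time-to-peak) and the true peak amplitude of every event.
    """
    rng = np.random.default_rng(cfg.seed)
    rate = cfg.rate_hz
    n = int(round(cfg.duration_s * rate))
    t = np.arange(n) / rate

    trace = cfg.drift_amp_pA * np.sin(2 * np.pi * t / max(cfg.duration_s, 1e-9))
    if cfg.noise_sd_pA > 0:
        sigma_t = 1.0 / (2 * np.pi * cfg.noise_bandwidth_hz)
        noise = gaussian_filter1d(rng.standard_normal(n), sigma_t * rate)
        trace += noise * (cfg.noise_sd_pA / np.std(noise))

    kernel = ipsc_kernel(cfg.rise_ms, cfg.decay_ms, rate)
    tr, td = cfg.rise_ms * 1e-3, cfg.decay_ms * 1e-3
    t_peak = tr * td / (td - tr) * np.log(td / tr)

    onsets = _poisson_times(cfg.event_rate_hz, 0.0,
                            max(cfg.duration_s - 8 * td, 0.0), rng)
    if cfg.amp_cv > 0:
        s2 = np.log(1 + cfg.amp_cv ** 2)
        amps = rng.lognormal(np.log(cfg.amp_mean_pA) - s2 / 2, np.sqrt(s2),
                             size=onsets.size)
    else:
        amps = np.full(onsets.size, cfg.amp_mean_pA)

    for t0, a in zip(onsets, amps):
        i0 = int(round(t0 * rate))
        seg = min(kernel.size, n - i0)
        trace[i0:i0 + seg] += cfg.polarity * a * kernel[:seg]

    gt = EventTable(onset_s=onsets, peak_s=onsets + t_peak,
                    offset_s=onsets + 8 * td, amplitude=amps) if onsets.size \
        else EventTable.empty()
    return UniformSignal(trace, rate, units="pA"), gt


# ---------------------------------------------------------------------------
# fiber photometry


@dataclass(frozen=True)
class PhotometrySimConfig:
    """Two-channel photometry session with locomotion-coupled activity.

    The 465 nm channel is ``bleach × (1 + activity) + artifact + noise``, the
    405 nm isosbestic channel ``bleach × c405 + artifact + noise`` with the
    identical bleach trend and motion artifact.  Activity is
    ``max(coupling_gain × acceleration, 0)`` convolved with a unit-peak GCaMP
    kernel (0.2 s rise, 0.7 s decay).
    """

    duration_s: float = 300.0
    rate_hz: float = 1000.0
    frame_rate_hz: float = 15.0
    coupling_gain: float = 0.05       # fractional ΔF per m/s²
    gcamp_rise_s: float = 0.2
    gcamp_decay_s: float = 0.7
    bleach_tau_s: float = 2000.0
    artifact_amp: float = 0.005       # shared additive artifact (a.u.)
    noise_sd: float = 0.002           # per-channel sensor noise (a.u.)
    bout_rate_hz: float = 0.05
    bout_duration_s: float = 6.0
    bout_ramp_s: float = 1.0
    peak_speed_mps: float = 0.15
    spont_rate_hz: float = 0.3        # movement-independent calcium transients
    spont_amp: float = 0.03           # their fractional ΔF amplitude
    f0_465: float = 1.0
    c405: float = 0.6
    arena_size_m: tuple[float, float] = (0.35, 0.24)
    seed: int = 0


def _gcamp_kernel(cfg: PhotometrySimConfig) -> np.ndarray:
    t = np.arange(0, int(round(6 * cfg.gcamp_decay_s * cfg.rate_hz))) / cfg.rate_hz
    k = np.exp(-t / cfg.gcamp_decay_s) - np.exp(-t / cfg.gcamp_rise_s)
    return k / np.max(k)


def _speed_profile(cfg: PhotometrySimConfig, rng: np.random.Generator
                   ) -> tuple[np.ndarray, IntervalSet]:
    """Trapezoidal speed bouts at Poisson times (sharp onsets, non-overlapping)."""
    n = int(round(cfg.duration_s * cfg.rate_hz))
    speed = np.zeros(n)
    starts = _poisson_times(cfg.bout_rate_hz, 1.0,
                            max(cfg.duration_s - cfg.bout_duration_s - 1.0, 1.0), rng)
    starts = _thin_refractory(starts, cfg.bout_duration_s + 1.0)
    nb = int(round(cfg.bout_duration_s * cfg.rate_hz))
    nr = int(round(cfg.bout_ramp_s * cfg.rate_hz))
    profile = np.ones(nb)
    profile[:nr] = np.linspace(0, 1, nr)
    profile[-nr:] = np.linspace(1, 0, nr)
    bouts = []
    for s in starts:
        i0 = int(round(s * cfg.rate_hz))
        speed[i0:i0 + nb] = cfg.peak_speed_mps * profile
        bouts.append((s, s + cfg.bout_duration_s))
    return speed, IntervalSet(bouts)


def photometry_channels(activity: np.ndarray, cfg: PhotometrySimConfig,
                        rng: np.random.Generator
                        ) -> tuple[UniformSignal, UniformSignal]:
    """Build the 465/405 channel pair around a given fractional activity trace."""
    n = activity.size
    t = np.arange(n) / cfg.rate_hz
    bleach = np.exp(-t / cfg.bleach_tau_s)
    artifact = np.zeros(n)
    if cfg.artifact_amp > 0:
        artifact = gaussian_filter1d(rng.standard_normal(n), 0.2 * cfg.rate_hz)
        artifact *= cfg.artifact_amp / np.std(artifact)
    f465 = cfg.f0_465 * bleach * (1.0 + activity) + artifact
    f405 = cfg.f0_465 * cfg.c405 * bleach + artifact
    if cfg.noise_sd > 0:
        f465 = f465 + rng.normal(0, cfg.noise_sd, n)
        f405 = f405 + rng.normal(0, cfg.noise_sd, n)
    return (UniformSignal(f465, cfg.rate_hz, units="a.u."),
            UniformSignal(f405, cfg.rate_hz, units="a.u."))


def simulate_photometry(cfg: PhotometrySimConfig
                        ) -> tuple[UniformSignal, UniformSignal, Track, dict]:
    """Simulate a session; returns (f465, f405, track, ground_truth).

    ``ground_truth`` holds the programmed activity trace, the speed profile
    at the photometry rate, and the mobility bout schedule.
    """
    rng = np.random.default_rng(cfg.seed)
    speed, bouts = _speed_profile(cfg, rng)
    accel = np.gradient(speed) * cfg.rate_hz
    drive = np.clip(cfg.coupling_gain * accel, 0.0, None)
    kernel = _gcamp_kernel(cfg)
    ksum = float(kernel.sum())
    # movement-independent (spontaneous) transients: without them every
    # session would be perfectly locomotion-locked, which no real PV-IN is
    for t0 in _poisson_times(cfg.spont_rate_hz, 0.0, cfg.duration_s, rng):
        i = int(round(t0 * cfg.rate_hz))
        if i < drive.size:
            drive[i] += cfg.spont_amp * ksum
    # normalized so sustained acceleration a settles at gain*a fractional ΔF
    # and each spontaneous transient peaks at spont_amp
    activity = np.convolve(drive, kernel / ksum)[:speed.size]
    f465, f405 = photometry_channels(activity, cfg, rng)

    # track positions consistent with the speed profile at the frame rate
    n_frames = int(np.floor(cfg.duration_s * cfg.frame_rate_hz))
    frame_idx = np.round(np.arange(n_frames) * cfg.rate_hz / cfg.frame_rate_hz).astype(int)
    v = speed[np.clip(frame_idx, 0, speed.size - 1)]
    heading = np.cumsum(rng.normal(0, 0.3, n_frames))
    w, h = cfg.arena_size_m
    x, y = np.empty(n_frames), np.empty(n_frames)
    x[0], y[0] = w / 2, h / 2
    dt = 1.0 / cfg.frame_rate_hz
    for i in range(1, n_frames):
        nx = x[i - 1] + v[i - 1] * dt * np.cos(heading[i - 1])
        ny = y[i - 1] + v[i - 1] * dt * np.sin(heading[i - 1])
        # reflect at the walls, preserving step length
        if nx < 0:
            nx = -nx
        if nx > w:
            nx = 2 * w - nx
        if ny < 0:
            ny = -ny
        if ny > h:
            ny = 2 * h - ny
        x[i], y[i] = nx, ny
    track = Track(np.arange(n_frames) / cfg.frame_rate_hz, x, y, cfg.frame_rate_hz)

    gt = {"activity": activity, "speed": speed, "mobility": bouts}
    return f465, f405, track, gt


# ---------------------------------------------------------------------------
# novel-object-location tracks


def simulate_nol_track(cfg: NolConfig, bias: float = 0.0, duration_s: float = 600.0,
                       frame_rate_hz: float = 15.0, seed: int = 0
                       ) -> tuple[Track, pd.DataFrame]:
    """Open-field random walk with optional extra dwell near object 0.

    ``bias`` in [0, 1) slows the walk inside object 0's exploration zone
    (longer dwell, hence more exploration time).  Ground truth is the exact
    per-object zone time and entry count under the annulus membership rule
    (distance in ``[radius, radius + zone_width)``).
    """
    if not (0 <= bias < 1):
        raise ValueError("bias must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * frame_rate_hz))
    w, h = cfg.arena_size_m
    inner = cfg.object_radius_m
    outer = inner + cfg.zone_width_m
    step_sd = 0.02  # m per frame, mouse-like exploration speed at 15 fps

    x, y = np.empty(n), np.empty(n)
    x[0], y[0] = w / 2, h / 2
    steps = rng.normal(0, step_sd, size=(n - 1, 2))
    cx0, cy0 = cfg.object_centers_m[0]
    for i in range(1, n):
        d0 = np.hypot(x[i - 1] - cx0, y[i - 1] - cy0)
        scale = (1.0 - bias) if inner <= d0 < outer else 1.0
        nx = x[i - 1] + scale * steps[i - 1, 0]
        ny = y[i - 1] + scale * steps[i - 1, 1]
        if nx < 0:
            nx = -nx
        if nx > w:
            nx = 2 * w - nx
        if ny < 0:
            ny = -ny
        if ny > h:
            ny = 2 * h - ny
        x[i], y[i] = np.clip(nx, 0, w), np.clip(ny, 0, h)
    track = Track(np.arange(n) / frame_rate_hz, x, y, frame_rate_hz)

    rows = []
    for k, (cx, cy) in enumerate(cfg.object_centers_m):
        d = np.hypot(x - cx, y - cy)
        m = (d >= inner) & (d < outer)
        entries = int(np.count_nonzero(np.diff(np.r_[False, m].astype(np.int8)) == 1))
        rows.append({"object": k, "time_s": float(np.count_nonzero(m)) / frame_rate_hz,
                     "entries": entries})
    return track, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# staining images


@dataclass(frozen=True)
class StainSimConfig:
    """Synthetic confocal field with labeled somata, rings and mRNA dots."""

    image_size_px: int = 512
    pixel_size_um: float = 0.5
    n_cells: int = 30
    soma_radius_um: float = 5.0
    cell_intensity: float = 150.0              # soma channel
    stain_intensity_mean: float = 100.0        # graded somatic stain
    stain_intensity_sd: float = 30.0
    ring_fraction: float = 0.83
    ring_intensity: float = 120.0
    ring_width_um: float = 3.8
    dot_radius_um: float = 0.5
    dot_intensity: float = 200.0
    dot_density_in_per_um2: float = 0.02
    dot_density_out_per_um2: float = 0.001
    background: float = 10.0
    noise_sd: float = 0.0
    seed: int = 0
    max_place_tries: int = 2000

    def __post_init__(self) -> None:
        if self.dot_density_in_per_um2 < 0 or self.dot_density_out_per_um2 < 0:
            raise ValueError("dot densities must be >= 0")
        if not (0 <= self.ring_fraction <= 1):
            raise ValueError("ring_fraction must be in [0, 1]")


def _disk(shape: tuple[int, int], cx: float, cy: float, r_px: float) -> np.ndarray:
    yy, xx = np.ogrid[:shape[0], :shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px ** 2


def simulate_stain_image(cfg: StainSimConfig) -> tuple[AnnotatedImage, pd.DataFrame]:
    """Synthesize channels "PV", "arom", "WFA", "dots" plus the cell label mask.

    Ground truth records each cell's programmed somatic stain intensity, ring
    presence, exact in-cell dot count, and pixel area.  In-cell dots are
    placed fully inside their soma and pairwise non-overlapping, so that
    noise-free connected-component counting recovers the programmed count
    exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    size = cfg.image_size_px
    px = cfg.pixel_size_um
    r_px = cfg.soma_radius_um / px
    ring_px = cfg.ring_width_um / px
    shape = (size, size)

    # non-overlapping somata (rings must not overlap either)
    centers: list[tuple[float, float]] = []
    min_sep = 2 * (r_px + ring_px) + 2
    margin = r_px + ring_px + 2
    tries = 0
    while len(centers) < cfg.n_cells:
        tries += 1
        if tries > cfg.max_place_tries:
            raise RuntimeError(
                f"could not place {cfg.n_cells} non-overlapping cells in "
                f"{size}x{size} px after {cfg.max_place_tries} tries")
        cx = rng.uniform(margin, size - margin)
        cy = rng.uniform(margin, size - margin)
        if all((cx - a) ** 2 + (cy - b) ** 2 >= min_sep ** 2 for a, b in centers):
            centers.append((cx, cy))

    labels = np.zeros(shape, dtype=np.int32)
    pv = np.full(shape, cfg.background, dtype=np.float64)
    arom = np.full(shape, cfg.background, dtype=np.float64)
    wfa = np.full(shape, cfg.background, dtype=np.float64)
    dots = np.full(shape, cfg.background, dtype=np.float64)

    stain_vals = np.clip(rng.normal(cfg.stain_intensity_mean, cfg.stain_intensity_sd,
                                    cfg.n_cells), 0, None)
    has_ring = rng.random(cfg.n_cells) < cfg.ring_fraction

    dot_r_px = max(cfg.dot_radius_um / px, 1.0)
    rows = []
    for k, (cx, cy) in enumerate(centers, start=1):
        cell = _disk(shape, cx, cy, r_px)
        labels[cell] = k
        pv[cell] = cfg.cell_intensity
        arom[cell] = stain_vals[k - 1]
        if has_ring[k - 1]:
            ring = _disk(shape, cx, cy, r_px + ring_px) & ~_disk(shape, cx, cy, r_px)
            wfa[ring] = cfg.ring_intensity

        # in-cell dots: fully inside the soma, pairwise non-overlapping
        area_um2 = np.count_nonzero(cell) * px ** 2
        n_dots = rng.poisson(cfg.dot_density_in_per_um2 * area_um2)
        placed: list[tuple[float, float]] = []
        attempts = 0
        while len(placed) < n_dots and attempts < 200 * max(n_dots, 1):
            attempts += 1
            rho = (r_px - dot_r_px - 1) * np.sqrt(rng.random())
            phi = rng.uniform(0, 2 * np.pi)
            dx, dy = cx + rho * np.cos(phi), cy + rho * np.sin(phi)
            if all((dx - a) ** 2 + (dy - b) ** 2 > (2 * dot_r_px + 1) ** 2
                   for a, b in placed):
                placed.append((dx, dy))
        for dx, dy in placed:
            dots[_disk(shape, dx, dy, dot_r_px)] = cfg.dot_intensity
        rows.append({"cell": k, "cx_px": cx, "cy_px": cy,
                     "radius_um": cfg.soma_radius_um,
                     "stain_intensity": float(stain_vals[k - 1]),
                     "has_ring": bool(has_ring[k - 1]),
                     "n_dots": len(placed),
                     "area_px": int(np.count_nonzero(cell)),
                     "area_um2": float(area_um2)})

    # extracellular dots, kept clear of every soma
    outside_area_um2 = (labels == 0).sum() * px ** 2
    n_out = rng.poisson(cfg.dot_density_out_per_um2 * outside_area_um2)
    placed_out = 0
    attempts = 0
    while placed_out < n_out and attempts < 200 * max(n_out, 1):
        attempts += 1
        dx, dy = rng.uniform(0, size), rng.uniform(0, size)
        if all((dx - a) ** 2 + (dy - b) ** 2 > (r_px + dot_r_px + 2) ** 2
               for a, b in centers):
            dots[_disk(shape, dx, dy, dot_r_px)] = cfg.dot_intensity
            placed_out += 1

    if cfg.noise_sd > 0:
        for ch in (pv, arom, wfa, dots):
            ch += rng.normal(0, cfg.noise_sd, shape)
            np.clip(ch, 0, None, out=ch)

    img = AnnotatedImage(channels={"PV": pv, "arom": arom, "WFA": wfa, "dots": dots},
                         pixel_size_um=px, roi_masks=labels)
    return img, pd.DataFrame(rows)
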