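# Methods

`hippoquant` re-implements, as a tested library, the quantitative analysis
stages of a hippocampal-inhibition study design: spontaneous IPSC detection
from voltage-clamp traces, sharp-wave-ripple (SWR) detection and SD-unit power
from the CA1 pyramidal-layer LFP, theta/gamma band-power estimation,
isosbestic-corrected fiber photometry with locomotion coupling,
novel-object-location (NOL) scoring, and staining/colocalization
quantification. Because no recordings of this kind are bundled with the
package, a seeded synthetic-data module generates every input class with known
ground truth; all quantitative claims below are checked by the test suite and
recomputed by `scripts/acceptance.py`.

## Shared conventions

Time is in seconds; sample `i` of a uniformly sampled signal occurs at
`t0 + i/rate`. Intervals are half-open `[start, end)`, so adjacent intervals
never double-count samples, and a sample belongs to an interval iff
`start <= t < end` on its exact timestamp. Event tables carry
`onset <= peak <= offset` and are sorted by onset. Signals are stored in HDF5,
tables and interval sets in CSV, images in TIFF, configs in YAML.

## IPSC detection (`hippoquant.ipsc`)

Events are detected by a threshold trigger on a differentiated copy of the
current trace: the first difference scaled to pA/ms, boxcar-smoothed (default
2 ms), must exceed `derivative_threshold` (default 10 pA/ms) continuously for
`trigger_duration_ms` (default 0.5 ms). Outward currents at a 0 mV holding
potential give the default polarity of +1. Amplitude is measured from the
median of a 5 ms pre-onset baseline to the extremum of a lightly smoothed
(1 ms boxcar) copy within 10 ms of onset; without that smoothing the extremum
rides the in-window noise maximum and amplitudes bias high by ~15 % at
5 pA noise.

Two guards shape the trigger. A 2 ms refractory suppresses immediate
re-triggers, and a Schmitt-style re-arm requires the derivative to fall below
`rearm_level` (default 0 pA/ms — the trace must stop rising) before a new
event may fire. The re-arm makes the event count provably monotone in the
threshold: every higher-threshold event nests inside a lower-threshold run,
so raising the threshold can only remove events. Detection thresholds are
per-cell tuning parameters in practice; the summary output therefore echoes
the parameter set used.

Detector defaults were set against the synthetic trace model: 5 Hz trains of
50 pA biexponential events (0.5 ms rise, 10 ms decay, log-normal amplitudes,
CV 0.3) in 5 pA band-limited noise yield recall ≥ 0.95 at zero measured false
rate, frequency within 5 % and mean amplitude within 10 %.

## SWR detection (`hippoquant.swr`)

The chain is band-pass 70–250 Hz → rectify → Gaussian smooth → threshold in
baseline-SD units:

* **Filter.** A zero-phase symmetric Hamming-window FIR whose tap count is set
  from the low band edge, reaching ≥ 40 dB attenuation by 0.8×70 Hz and
  1.2×250 Hz at any sampling rate (verified by a frequency-response test).
  Zero phase keeps event times unbiased.
* **Envelope.** Gaussian smoothing (SD 8 ms) of the rectified filtered signal.
  A rectified band-passed oscillation must be smoothed over at least the band
  noise correlation time (~5 ms for 70–250 Hz) or the envelope inside one
  genuine burst fragments; 4 ms kernels lose half the 4.5 SD events for this
  reason, while 8 ms (a little over one ripple cycle) keeps within-burst
  continuity at negligible cost in time resolution.
* **Baseline.** Envelope mean and SD over immobility ("non-movement") periods,
  single pass, detected events included. At least 10 s of immobility is
  required. All per-event powers (mean and max of the standardized envelope)
  are reported in these SD units, which makes every output invariant to
  rescaling the raw voltage.
* **Events.** Maximal runs with z > 3 (default) are candidates. Runs closer
  than the 15 ms merge gap whose interposed envelope stays above the 1 SD
  boundary are bridged (fragments of one burst stay elevated between
  fragments; independent noise spikes do not). The ≥ 20 ms minimum duration
  applies to this supra-threshold core: applying it after boundary extension
  would pass essentially any noise spike, since extension to 1 SD stretches
  every excursion past 20 ms (measured 0.43 Hz false rate on pure noise,
  versus 0.01 Hz with the core gate). Surviving cores are extended outward to
  the 1 SD crossings to define onset/offset, and events longer than 250 ms are
  discarded.
* **Rate.** Events whose peak lies in immobility per second of immobility
  (SWRs are an immobility phenomenon); a total-time denominator is available
  by flag.
* **Common threshold.** For longitudinal comparisons, baseline stats can be
  pooled over the immobility envelopes of several sessions (equivalent to
  concatenating the recordings) and detection run per session with the shared
  mu/SD, so rate differences cannot come from per-session threshold
  differences.

## Spectral analysis (`hippoquant.spectral`)

Spectra are Welch averages of Hamming-windowed periodograms at 0.5 Hz
resolution (2 s windows, 50 % overlap, no detrending), one-sided density
normalization (integral ≈ variance; Parseval-checked to 5 %). Band power sums
density × bin width over half-open bands, so slow gamma (30–60) and fast gamma
(60–90) tile gamma (30–90) exactly. Mains contamination is handled in the
spectral domain: bins within ±2 Hz of 50 Hz and its harmonics are replaced by
linear interpolation of log power between the nearest untouched flanking bins
(log interpolation respects the 1/f background; a zero flank falls back to
linear). The 8 Hz/4 Hz theta ratio divides the densities of the single 0.5 Hz
bins at exactly 8.0 and 4.0 Hz (an optional ±halfwidth band mode exists); a
zero denominator returns NaN.

Theta segments are a declared criterion, not a reconstruction: 2 s windows
stepped by 1 s are marked when theta-band (4–10 Hz) power exceeds twice the
1–4 Hz reference power; maximal unions of marked windows at least 3 s long are
kept. On synthetic LFP with movement-gated theta this recovers the programmed
mobility schedule with Jaccard ≥ 0.8.

## Fiber photometry (`hippoquant.photometry`)

ΔF/F is the fractional residual of a whole-session least-squares affine map of
the isosbestic (405 nm) channel onto the calcium (465 nm) channel, in percent.
This removes shared bleaching and motion artifacts and is zero-mean by
construction; a zero-variance 405 channel is a hard error. Mobility is
segmented by a 0.02 m/s speed threshold (1 s minimum bout, 0.5 s gap merge);
mobility and immobility partition the session exactly. Transition-triggered
averages z-score the signal per session, align snippets at the transition and
average pointwise with SEM; transitions whose window leaves the span are
dropped and counted.

Acceleration coupling: ΔF/F is z-scored and downsampled to the 15 frames/s
tracking timebase by windowed means (one frame period per window) rather than
upsampling kinematics — no sub-frame motion is invented. Instantaneous speed
is the frame-to-frame displacement times frame rate through a 3-frame median
filter (tracking jitter), acceleration its centered difference. The response
curve bins the (acceleration, z-ΔF/F) cloud into equal-count bins separately
for acceleration and deceleration. The per-animal modulation index fits
`y = a2 x² + a1 x + a0` by least squares and reports
`index = ŷ(+a_ref) − ŷ(−a_ref) = 2 a1 a_ref` with `a_ref` the 95th percentile
of |acceleration| — a scalar that is zero for an acceleration-blind signal,
antisymmetric in the coupling, and equal to `2 g a_ref` for exact linear
coupling `y = g x`. The raw coefficients are returned so alternative summaries
can be derived.

## Behavior (`hippoquant.behavior`)

NOL exploration is scored as frame membership in the 2 cm-wide annulus between
an object's footprint and footprint + zone width (the animal cannot occupy the
object interior); an entry is the first frame of each maximal in-zone run. The
discrimination index is `(displaced − familiar)/(displaced + familiar)`
exploration time, bounded in [−1, 1], antisymmetric, NaN (excluded) when total
exploration is zero. Entry counts are reported alongside for analyses that
prefer them. The default arena is the 0.35 × 0.24 m open field.

## Histology (`hippoquant.histology`)

All intensity measures run on batch-thresholded images: one common threshold
per channel across a batch, sub-threshold pixels zeroed, means taken over all
ROI pixels (a suprathreshold-only mode exists). The perineuronal ring is the
set of pixels outside a cell whose Euclidean distance (distance transform,
physical units) to the cell is below the ring width (default 3.8 µm); rings
reaching the image border are flagged clipped. Dot surface density binarizes
the channel at the batch threshold and counts connected components within the
ROI of at least `dot_min_area_um2`, per µm² of ROI; the suprathreshold area
fraction is reported alongside because "surface density" admits both readings.
Chance colocalization re-measures after mirror-flipping the signal channel
(ROIs untouched); a 180° rotation mode is provided as an alternative.
Cumulative distributions are computed per animal on a common 18-bin grid
spanning the pooled range, then averaged pointwise across animals with SEM.

## Synthetic data (`hippoquant.synth`)

All generators are pure functions of (config, seed), and each ground truth
suffices to score its detector without re-reading the raw signal.

* **LFP.** 1/f-shaped Gaussian noise (exponent 1.0, 0.1 mV SD) plus
  movement-gated 8 Hz theta (0.3 mV, with a co-scaling 4 Hz component at half
  amplitude, so the 8/4 power ratio is a waveform-shape constant) and
  band-limited 30–90 Hz gamma (0.03 mV RMS). Shaped noise is normalized by its
  analytic expected variance, not per realization, so independent sessions are
  draws from the identical process. Ripples are Gaussian-enveloped 150 Hz
  bursts (envelope SD 20 ms) at Poisson times inside immobility, dead-time
  corrected for the 200 ms refractory so the post-thinning ground-truth rate
  equals the configured rate. Ripple amplitude is specified in analysis-
  envelope SD units and realized per event by a secant calibration against the
  detection chain itself, with baseline stats re-estimated from the injected
  signal exactly as the analysis will compute them — programmed SD-units
  therefore equal measured SD-units by construction.
* **IPSC traces.** Slow sinusoidal drift, band-limited Gaussian noise
  (≈ 2 kHz equivalent cutoff — acquisition chains low-pass filter before
  digitizing; unfiltered white noise at 20 kHz would make any derivative
  trigger physically hopeless), and Poisson biexponential events normalized to
  unit peak with log-normal amplitudes.
* **Photometry.** Trapezoidal speed bouts (0.05 Hz, 6 s, 1 s ramps, 0.15 m/s
  peak) drive activity = max(gain × acceleration, 0) filtered by a unit-peak
  GCaMP kernel (0.2 s rise, 0.7 s decay, normalized so sustained acceleration
  settles at gain × a fractional ΔF). Movement-independent spontaneous
  transients (0.3 Hz, 3 % ΔF/F) provide the non-locomotor variance every real
  session has; without them session z-scoring makes the modulation index
  exactly gain-invariant and condition comparisons meaningless. Both channels
  share the bleach trend and additive artifact; the track integrates the speed
  profile along a random heading with wall reflection.
* **NOL tracks.** Gaussian-step random walk (0.02 m/frame SD) with wall
  reflection; dwell bias shortens steps inside the displaced object's zone.
  Ground truth applies the same annulus rule as the scorer, so recovery is
  exact.
* **Stain images.** Non-overlapping somata (radius 5 µm) on a 512² grid at
  0.5 µm/px; per-cell graded stain intensities, perineuronal rings on a
  configurable fraction of cells, and ~1 µm dots at programmed densities
  inside (fully inside, pairwise non-overlapping — so noise-free component
  counting is exact) and outside cells.

## Problem sizes and numerical choices

Simulation-based tests run the LFP model at 2 kHz (the 70–250 Hz band has a
4× Nyquist margin there) and 600 s, photometry at 1 kHz and 300 s, IPSC traces
at the hardware 20 kHz and 120 s; direction analogues use 20 seeds per
comparison. Config defaults keep the hardware rates (20 kHz LFP/IPSC). Filter
tap counts scale with sampling rate; envelope and spectral estimates at 2 kHz
and 20 kHz agree to within the stated tolerances. Degenerate inputs error
early: empty tracks, zero-variance isosbestic channels, one-signed
acceleration, immobility under 10 s, bands outside the spectrum, notches at
the spectrum edge.

## What the synthetic tests do and do not show

Passing recovery tests shows the detectors measure what the generators
programmed under realistic noise, at the stated effect sizes — not that the
generators capture every property of real recordings. The LFP model has no
sharp-wave component below the ripple band, no CSD structure, and stationary
noise; the IPSC model has no series-resistance drift or overlapping-burst
kinetics; the photometry model's artifact is additive and shared exactly;
open-field tracks have no thigmotaxis or grooming; stain images have ideal
disk somata. Direction analogues (rate/power, band power, modulation index)
establish that condition differences of the simulated size survive the full
pipeline in ≥ 19/20 seeded replicates; they say nothing about group-level
inference, which is deliberately left to external statistics tools operating
on the tidy per-unit tables this package emits.
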