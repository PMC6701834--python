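# Methods

## Signal model

A recording is a channels × samples matrix of extracellular voltage (µV) at
a fixed sampling rate, nominally 20 kHz. During two-photon imaging the
measured voltage is modelled as

    x_c(t) = n_c(t) + Σ_u Σ_i w_u(t − t_{u,i}) + s_c · a(t) · 1[laser on]

with `n_c` Gaussian background noise, `w_u` the biphasic template of unit
`u` inserted at Poisson event times `t_{u,i}` (2 ms enforced dead time), and
`a(t)` the photoelectric artifact scaled per channel by `s_c`. The artifact
is strictly periodic at the imaging frame rate `f_r` (default 15.5 Hz) and
has two parts:

* a **band-limited sawtooth**: sine harmonics at `k·f_r` with amplitude
  ∝ 1/k, restricted to the 300–3000 Hz single-unit band and rescaled so the
  summed waveform's peak equals the configured amplitude. Restricting the
  series to the analysis band reflects the effectively capacitive coupling
  of the photoelectric transient into the electrode: the sharp per-frame
  flyback excites the band densely while the slow ramp (low harmonics) is
  strongly suppressed. It also keeps the removal problem well posed — a
  comb restricted to 300–3000 Hz cannot, by construction, reject lines
  outside that range, and the 2nd-order band-pass barely attenuates a line
  a few Hz below its edge (≈ −1 dB at 294.5 Hz); `fit_comb_filter` detects
  that situation and aborts with a diagnostic rather than loop forever.
* a **per-frame transient**: a Gaussian-windowed 1.2 kHz tone burst of total
  width 5.5 ms placed mid-frame, emulating the brief spike-like artifacts
  that accompany each frame. The width is calibrated so
  `width × frame rate ≈ 8.5%` of the signal is affected.

Default study conditions: 60 s, 4 channels, 20 kHz; two units with trough
amplitudes 150 and 60 µV firing at 5 and 8 Hz; noise SD 6 µV (a typical
band-passed extracellular noise floor); laser on during the middle third
(mirroring an off/on/off protocol); artifact peak = 50 × the largest
template trough; per-channel artifact scales (1.0, 0.8, 0.65, 0.5);
transient amplitude 300 µV. Noise, spike trains and artifact use independent
seeded RNG streams, so zeroing one component leaves the others bit-identical
(additivity), and the whole generator is reproducible from a single seed.

What the generator does **not** model: line-scan substructure within a
frame, slow drift of electrode position or artifact amplitude, non-Gaussian
noise, bursting or rate non-stationarity, waveform variability within a
unit, and frame-rate jitter of the scanner. Tests passing on this generator
therefore demonstrate the algorithm's correctness under stationary periodic
contamination, not robustness to every property of real recordings.

## Comb-filter parameter setting

Per channel, on the 300–3000 Hz band-passed contaminated signal:

1. `D_F` (inter-peak spacing) is estimated once from the initial spectrum
   and frozen. Detected peaks are local maxima above both 5× the median
   in-band magnitude and 2% of the in-band maximum (the second floor rejects
   the spike train's own spectral fluctuations, which exceed the
   noise-dominated median on long segments). The estimate starts from the
   median of consecutive peak spacings and is refined by regressing peak
   frequency on harmonic index — first telescoped across the longest run of
   regular spacings, then least-squares on grid-snapped peaks. The
   refinement matters: the median alone is quantized to the FFT bin grid,
   and a bin-sized period error accumulates over the hundreds of artifact
   periods a recording spans, smearing the period fold beyond use.
2. The residual periodic amplitude is measured by folding the signal over
   the (generally non-integer) period `f_s / D_F` into `round(period)` phase
   bins (~one sample wide) and taking the per-bin **median** across periods;
   the result is the peak |folded waveform|. The median suppresses spikes
   (random phases) and noise while preserving sharp periodic waveforms; a
   coarser binning would average away the up-to-3 kHz ringing of the
   band-passed tooth and under-report the residual.
3. While the residual is ≥ 40 µV: FFT the residual (Hann-windowed — the
   artifact lines are ~50× everything else and rectangular-window leakage
   skirts would masquerade as peaks), centre a module on the highest in-band
   peak, cover the contiguous neighbours at `f_peak ± n·D_F` exceeding 15%
   of the centre (strict >; each element centred on the measured local
   maximum within one bin of the nominal position), notch each with a
   band-stop at ±3 Hz, apply the new module to the running residual, repeat.
   Zero-phase SOS cascades commute, so filtering the running residual with
   each new module equals applying the full comb to the original signal.
4. Safety rails: at most 50 modules, and abort with partial results if the
   residual improves by < 1% over three consecutive cycles.

## Filter design

All filters are Chebyshev type I in second-order-section form (direct-form
coefficients of a 6 Hz notch at 20 kHz are ill-conditioned), 0.4 dB passband
ripple (the ripple value interpreted in dB, the conventional unit), applied
with forward–backward (`sosfiltfilt`) filtering and odd-reflection padding:
zero net phase, squared magnitude response, no trough displacement.

The band-pass is 2nd order, 300–3000 Hz. **Comb elements are order 1** (one
biquad notch each). This is a hard numerical constraint, not a taste choice:
even-order Chebyshev-I sections have gain −Rp at their passband peaks
(including DC and far passband), so each order-2 element would contribute
~−0.8 dB of broadband droop after zero-phase application, and a fitted comb
of ~170 elements would attenuate the entire band by ~130 dB. Odd-order
sections have unity passband peaks; the full 174-element comb changes a tone
midway between two notches by < 10%, while attenuating each covered line by
effectively the full notch depth.

Filtering is applied to laser-on and laser-off stretches as separate pieces.
The artifact's on/off step would otherwise ring through the narrow notches
(impulse-response time constant ≈ 1/(π·3 Hz) ≈ 106 ms) and litter the
transition neighbourhoods with threshold crossings; the pipeline additionally
discards detections within 0.5 s (~5 time constants) of a piece boundary.

## Spike detection, features, sorting

Threshold: −5 × MAD-based noise sigma (`median(|x|)/0.6745`), negative
crossings aligned to the local minimum within ±0.5 ms, 1 ms dead time
keeping the deeper trough, 0.8 ms windows. Features: `v_trough` plus the
values `round(250 µs × f_s)` samples (5 at 20 kHz) before and after the
trough — the trough *value* reading; the alternative reading of feature 1
as the trough's time index is a one-line variant not taken.

Sorting is a seeded k-means partition in the 3-feature space, standing in
for manual cluster curation. One repair step follows: clusters whose mean
trough depths differ by < 3 pooled within-cluster trough SDs are merged.
k-means always splits even a single unit's cloud — one sample of trough
alignment jitter moves the flank features by a full slope step, producing
discrete sub-modes — but jitter leaves the trough value itself untouched,
whereas genuinely distinct units differ in it by construction of the
3-feature method. The known blind spot (two real units with equal trough
depth but different shape would be merged) is shared with any
amplitude-dominated sorting and is why the PCA cross-check route exists.

## Validation battery

Per-unit, per-minute (non-overlapping 60 s bins) means and SEMs of the three
features plus spike counts; laser-on vs laser-off comparison in pooled-SEM
units plus rate ratios and normalised autocorrelogram differences; and the
laser-phase histogram of spike times within the frame period (20 bins over
one period), with the frame clock taken from ground truth when available or
derived from `D_F` otherwise. On laser-independent synthetic firing the
phase histogram is uniform (chi-square) and rate ratios sit in the Poisson
envelope; a constructed phase-locked modulation is detected as significant.

## Numerical choices and degenerate inputs

* Spectra require ≥ 2 s of signal (≤ 0.5 Hz resolution, needed to place
  ±3 Hz cutoffs); folding requires ≥ 20 periods; magnitude spectra are
  normalised to sinusoid amplitude so spectral peak heights compare directly
  with time-domain µV.
* A signal with no detectable periodic peaks (or an initial residual already
  below 40 µV) yields an empty comb, which applies as the identity.
* Segments are half-open `[start, end)`; sample indices 0-based;
  `time = index / f_s`.
* Recordings are stored as float32 little-endian channel-major flat binary
  with a JSON sidecar; units are µV only, never converted implicitly.

## Problem sizes

The shipped tests and the acceptance script run the full default conditions
(60 s × 4 channels × 20 kHz, ~5 M samples) for the convergence, detection
and suppression checks, and smaller purpose-built inputs (8–30 s, one
channel) for the component-level properties; the stability check uses five
artifact-free minutes. These sizes were chosen to exercise every code path at
full sampling rate while keeping the whole battery to a few minutes.

## Known limitations

* The comb rejects ~40% of the 300–3000 Hz band under the default artifact
  (174 × 6 Hz slivers); spike troughs shrink by ~1/3. Detection adapts (the
  threshold is noise-relative) and the distortion is condition-independent,
  but absolute amplitudes after filtering are not comparable with unfiltered
  recordings.
* Spikes themselves excite the narrow notches; each spike leaves a ±100 ms
  ring of a few µV, so trough measurements on dense trains carry extra
  variance, and overlapping spikes corrupt each other's features (the
  validation compares means, which absorb this symmetrically).
* Artifact energy outside the comb's 300–3000 Hz range is out of reach by
  design; choosing the comb's frequency range automatically is explicitly
  not attempted.
* Spike-like artifact transients synchronous with the laser that survive
  filtering are detected as events (the phase histogram exists to expose
  them); removing them via their synchrony is likewise not attempted.
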