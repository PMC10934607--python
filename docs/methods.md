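# Methods

## Problem and approach

Forcecardiography (FCG) records the forces that the beating heart and the
breathing chest wall exert on a force sensor placed on the thorax.  Its
high-frequency component (30–200 Hz) contains the first and second heart
sounds, S1 and S2.  This package localizes S1, S2 and whole S1–S2 pairs in
that component by normalized cross-correlation (NCC) template matching, and
evaluates the result against a simultaneous ECG: recognition statistics,
inter-beat-interval (IBI) agreement, and heart-rate-variability (HRV)
indices computed from both modalities.

The processing chain is:

1. **Respiration removal.** The respiratory component is estimated with a
   Savitzky–Golay smoother (frame ≈ 1.5 s, cubic polynomial) and subtracted;
   the decomposition `raw = respiration + cardiac` is exact by construction.
2. **Heart-sound isolation.** The cardiac component is band-passed
   30–200 Hz with a zero-phase Butterworth filter.  "4th order" follows the
   common `butter(4, [lo hi])` design idiom (4th-order low-pass prototype,
   8-pole band-pass); applied forward–backward, the magnitude response is
   squared and the group delay is zero, so event times stay on the raw
   clock.  We verified the alternative 2-pole-pair reading attenuates the
   ~50 Hz S1 carrier enough to distort the reconstructed sounds by > 5%
   RMS, which is why the sharper design is the default.
3. **ECG conditioning and R-peaks.** The ECG is band-passed 0.5–40 Hz and
   notched at the mains frequency and harmonics (Q = 30); the fundamental is
   notched even though it lies above the band edge, because the band-pass
   roll-off alone leaves ~15% of a strong 50 Hz interferent.  R-peaks come
   from the classic Pan–Tompkins stages (5–15 Hz band-pass, 5-point
   derivative, squaring, 150 ms integration, adaptive dual thresholds with
   search-back), refined to the conditioned ECG's local maximum within
   ±50 ms and separated by a 0.25 s refractory period.
4. **Template matching.** A template (one S1, one S2, or one S1–S2 pair,
   including short quiet tracts at both ends) is selected manually by span
   or automatically from short-time-energy bursts.  The zero-mean NCC is
   computed at every window position (FFT-accelerated, validated to 1e-9
   against a direct double-loop transcription of the formula); zero-variance
   windows map to 0.  Local maxima above a threshold are events, greedily
   accepted from the highest down with a minimum-distance suppression; each
   event time is re-aligned so it marks where the template's absolute
   maximum landed.  For a pair template the absolute maximum lies inside S1
   (the louder sound), so pair events are S1 fiducials.
5. **Scoring.** Detections are paired one-to-one with reference beats after
   subtracting a self-calibrated lag (median detection-minus-nearest-
   reference offset), accepting residuals ≤ 150 ms greedily by size;
   sensitivity = TP/(TP+FN), PPV = TP/(TP+FP).  IBIs touching a false
   positive or flanking a miss are excluded from agreement analyses but
   retained for HRV, where artifact correction handles them instead.

## Synthetic data

Real FCG recordings are not publicly deposited, so a generator provides the
test substrate with exact ground truth.  It emulates the second-order
structure the method relies on and nothing more:

- RR intervals: `RR_k = 60000/hr_mean + rsa_amp·sin(2π·resp_rate·t_k) + ε_k`
  with white Gaussian jitter ε and a 300 ms floor (bounded resampling).
- S1/S2 wavelets: Gaussian-modulated cosines (envelope SD = duration/6)
  whose signed maximum sits exactly on the ground-truth fiducial.  Defaults:
  S1 50 Hz / 100 ms / unit amplitude; S2 80 Hz / 80 ms / 0.6 amplitude,
  placed 300 ± 10 ms after S1.  The S2 carrier sits well above S1's because
  the aortic/pulmonic closure sounds are higher-pitched; with closer
  carriers the two wavelets are so NCC-similar (≈ 0.8) that no threshold
  can separate them, which no real recording analyzed with this method
  exhibits.
- Respiration: a 0.25 Hz baseline (amplitude 2) plus ±20% amplitude
  modulation of S2 — the mechanical counterpart of physiologic S2 splitting.
- Noise: white Gaussian, default SD 0.02 (2% of the S1 peak).
- ECG: a positive Ricker wavelet (scale 12.5 ms) at each R time, 50 ms
  before S1.

Everything stochastic flows from one seed (independent deterministic
streams per component), so identical configurations are bit-identical.

What the generator does *not* emulate: inter-subject morphology differences,
within-recording template drift, S3/S4 or murmurs, non-stationary noise,
sensor coupling changes, and continuous low-level cardiac vibration between
sounds.  The last point matters for interpretation: synthetic diastole is
silent up to white noise, which makes the NCC noise floor *higher* than on
real data (see below), so passing the recognition tests here does not
guarantee thresholds transfer to a given sensor unchanged — they are
configuration, as in the original method where findpeaks parameters were
chosen per recording.

## Matcher operating points

NCC is amplitude-invariant, so in quiet stretches it measures the match
between the template and noise alone; the maximum of that match over a
5-minute recording is ≈ 0.60 for the 120 ms S1 template and ≈ 0.72 for the
100 ms S2 template (shorter template, fewer effective degrees of freedom),
independent of the noise amplitude.  True matches score ≥ 0.96.  The
pipeline therefore uses per-label defaults: height 0.8 for S1 and S2.  The
450 ms pair template has a much lower noise ceiling (≈ 0.14) but its
true-match values drop to ≈ 0.43 when the systolic interval jitters (the
template's S2 half decorrelates), so the pair threshold is 0.3; the pair
also has a sidelobe one systolic interval away (its S1 half aligned with
the beat's S2), suppressed by a 0.5 s minimum distance (pair events recur
once per beat, ~0.9 s at rest).  `find_events` itself keeps the generic
0.5 / 0.3 s defaults; all operating points are configuration.

## Agreement statistics

- **Passing–Bablok**: slope = shifted median of the pairwise slopes
  (ties in x and slopes of exactly −1 excluded; offset K = #{S_ij < −1});
  even counts average the two central order statistics; 95% CIs from the
  rank-based normal approximation; intercept = median(y − slope·x) with CI
  from the slope CI bounds.  Validated against an O(n²) enumeration.
- **Cusum linearity**: residual signs walked in order of increasing x,
  max |cusum| / √(L+1) compared with the Kolmogorov–Smirnov-type critical
  value 1.22 (α = 0.10); "linear" means not rejected.
- **Pearson r** with Fisher-z 95% CI.
- **Bland–Altman**: Shapiro–Wilk (α = 0.05) gates the variant.  Normal:
  bias = mean, LoA = bias ± 1.96·SD (sample SD), t-based CI of the bias
  (SE = SD/√n) and of each LoA (SE = SD·√(3/n)).  Non-normal: bias =
  median, LoA = 2.5th/97.5th percentiles (linear-interpolation quantiles),
  CIs from a seeded 2000-resample bootstrap.

## HRV conventions

- Artifact correction: an interval deviating > 250 ms from the median of
  its 11-interval centered window is replaced by cubic-spline interpolation
  over the accepted intervals (single pass); > 20% flagged raises a quality
  warning.  FP/FN-affected intervals are *kept* for HRV (and corrected
  here), unlike the agreement analysis which drops them.
- Time domain: SDNN and SD HR use the sample SD (n−1); RMSSD is the
  uncentered root mean square of ΔRR; min/max HR are extremes of a 5-beat
  moving average; NN50/pNN50 count |ΔRR| > 50 ms.
- Frequency domain: cubic-spline resampling of RR(t) at 4 Hz, smoothness-
  priors detrending (λ = 500, sparse second-difference regularization),
  Hann-window Welch periodogram (segment 150 s or the record, 50% overlap),
  trapezoid band powers over VLF 0–0.04, LF 0.04–0.15, HF 0.15–0.4 Hz.
  Requires ≥ 120 s of intervals.
- Poincaré: SD1 = RMSSD/√2 exactly (uncentered convention — the centered
  variance breaks the identity whenever the series drifts); SD2 from
  2·SDNN² = SD1² + SD2²; ratio undefined (NaN) when SD1 = 0.
- Entropy: tolerance r = 0.2·SD(RR), Chebyshev distance; ApEn includes
  self-matches (Pincus), SampEn excludes them with both template lengths
  restricted to the first n−m vectors (Richman–Moorman); SampEn is NaN when
  no (m+1)-matches exist.  Both validated against a naive O(n²) counting
  implementation.
- DFA: integrated mean-centered RR, per-box linear detrending, α1 over box
  sizes 4–16 (needs ≥ 100 intervals), α2 over 16–64 (≥ 300); log–log
  least-squares slope.

## Problem sizes and numerical choices

The test-bench and the reproduction script use a 5-minute recording at
1 kHz (~300 beats, heart rate 65 bpm) — long enough for the 150 s spectral
window, ≥ 300 intervals for α2, and stable recognition statistics.  The
NCC uses FFT convolution with cumulative-sum window statistics; values are
clipped to [−1, 1] and windows whose variance falls below 1e-12 of the
signal scale return 0.  Peak ties break toward the earlier time.  Filters
run as second-order sections.  All bootstrap and generator randomness is
seeded.

## Known limitations

- Thresholds are operating points, not universal constants; real recordings
  need the same per-recording calibration the original workflow used.
- The S2/S1S2 interval agreement on synthetic data is dominated by the
  generator's systolic-interval jitter (LoA half-widths of ~20–27 ms at
  the default 10 ms jitter SD); this is physiology of the generator, not
  detector error — with the jitter disabled all three labels localize to
  within ±5 ms.
- Pan–Tompkins constants follow the classic description; toolbox-specific
  deviations are not replicated.
- Kubios-style correction and detrending use documented defaults; bit-exact
  replication of that software is a non-goal.
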