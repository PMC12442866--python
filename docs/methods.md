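# Methods

## The problem

When two sounds play at once, their neural responses overlap in time and
space. Frequency tagging separates them in the spectral domain: each
melody is amplitude-modulated at its own rate (39 Hz for the low-pitched
melody, 43 Hz for the high-pitched one), which drives an auditory
steady-state response (ASSR) phase-locked to the modulation envelope. The
power at each tag frequency then indexes the neural processing of that
melody alone, and selective attention toward a melody multiplies its tag
power. `assrtag` implements the full analysis chain — stimulus synthesis,
sensor-level simulation, the repeated-splitting decoder, time-resolved
attention measures, and the group statistics — for synthetic or
user-supplied multichannel epoch sets.

## Stimulus model

A tagged tone is `sin(2π f_c t) · e(t)` with envelope
`e(t) = (1 + m sin(2π f_m t)) / 2`. This peak-normalized form keeps the
waveform within ±1 and makes the modulation depth exactly
`m = (max − min)/(max + min)` of the envelope — the property the
depth-measurement routine and its tests rely on. Carriers default to
rounded equal-tempered C-major pitches in the 131–220 Hz (low) and
329–523 Hz (high) registers; tones last 2 s and melodies 8–26 s. Two
schedule designs exist: design I staggers onsets by half a tone so they
strictly alternate between streams (each onset opens a 1-s epoch in which
only one stream has a fresh onset), design II places every high onset
exactly on a low onset. Audio is synthesized at 44.1 kHz; the neural
sampling rate (1 kHz default) only needs to resolve the envelope-locked
components, not the carriers.

## Neural simulator

Each tagged component is a fixed-phase sinusoid at its tag frequency
(phase drawn once per simulation — ASSRs are phase-locked by definition,
and averaging only helps if phases agree across trials), projected to the
sensors through a per-tag spatial mixing pattern (standard-normal weights
drawn once, or user-supplied). Its amplitude is
`assr_amp × attention_gain^[attended] × g(t)`, where the optional
per-sample profile `g(t)` emulates attention that waxes or wanes within
the epoch. Background activity is white Gaussian noise plus 1/f^α noise
(α = 1 default), the canonical broadband MEG floor.

Default scales: `assr_amp = 0.05`, both noise SDs 1.0, `attention_gain =
2.0`. With 1-s epochs these put the single-epoch tag-bin SNR well below
one (the tag is invisible in a raw trial) while a ~46-epoch group average
brings it clearly above the noise floor — exactly the regime that
motivates split-averaging. Tag-bin power scales as the square of the
gain, so an attention gain g separates conditions by a factor g² in
feature space.

What the simulator does *not* emulate: cochlear or forward-model
physics, inter-channel noise correlations, artifacts (blinks, cardiac),
head movement, or any pitch-contour content (the decoder never sees
carriers). Tests passing on this generator therefore demonstrate the
correctness and calibration of the *analysis*, not performance on real
recordings.

## Repeated-splitting decoder

Per repetition: each condition's epochs are randomly partitioned into 5
near-equal groups (remainders spread one per group; every epoch used
exactly once) and averaged within groups; the 5+5 evoked responses are
tapered (Hann for the alternating design, boxcar for the coincident
design) and Fourier transformed at 1-Hz resolution; at every integer
frequency in 4–45 Hz independently, a binary linear SVM (C = 1) with
channels as features is cross-validated with stratified folds holding
one sample per condition, and scored by ROC AUC. The AUC is averaged
over 1000 repetitions (100 at desk scale).

Numerical choices worth knowing:

- **Taper normalization.** The Hann taper is scaled to unit mean, so an
  on-bin sinusoid has identical power under Hann and boxcar (the Hann
  DFT has support only at 0 and ±1 bins). Window choice then changes
  leakage behavior, not the scale of the classifier's inputs. A genuine
  on-bin component under Hann *does* smear into the two adjacent integer
  bins at amplitude ratio 1/2 — adjacent-bin AUC above chance under Hann
  is physics, not a bug.
- **Fold scoring.** Per-repetition AUC is the mean of per-fold test AUCs
  (`scoring="fold_mean"`, the `cross_val_score` idiom). The alternative
  of pooling all held-out decision scores into one ranking
  (`scoring="pooled"`) is available but measurably biased: at chance,
  scores produced by different fold classifiers are ranked against each
  other, inflating the null AUC by ≈ +0.02 (6σ over 3000 null
  replicates), whereas the fold-mean estimator is exactly unbiased
  because the two test samples of a fold are exchangeable given the
  training fold. With 1000 repetitions the coarse per-fold granularity
  ({0, ½, 1}) averages into a smooth estimate.
- **Standardization** uses training-fold statistics only (no leakage);
  zero-variance features get unit scale, which leaves truly constant
  features inert and the AUC at exactly 0.5 for all-tied scores
  (midrank convention).
- **Randomness.** Each repetition derives one random stream per
  condition from (master seed, repetition index, 64-bit data
  fingerprint). Streams follow the condition's data, not its argument
  position, so swapping the inputs reproduces identical partitions and
  the identical AUC — the decoder measures discriminability, which has
  no direction. Any repetition is individually reproducible.
- The channel-masked, tag-combined variant (`decode_tagged_features`)
  concatenates the power at all tag frequencies over a channel subset
  into one feature vector — the sensor-space analog of decoding from a
  cortical region of interest. With one tag and the full mask it reduces
  bit-exactly to the per-frequency decoder at that bin.

## Time-resolved analysis

A 1-s boxcar window slides over the 2-s tones in 50-ms steps (21 windows,
labeled by their **start time** relative to tone onset — this convention
determines what the 0.5-s attendee threshold means and is deliberately
explicit). The decoder runs per window and tag frequency; the peak
attention time is the window label of the global AUC maximum across both
tags, ties resolving to the earliest window. Listeners with peaks
strictly before 0.5 s are "early attendees", all others "late" (a peak
exactly at threshold is late). The lateness index
`(AUC_late − AUC_early)/(AUC_late + AUC_early)` is computed from static
decoding of the two 1-s tone halves rather than from the sliding
windows, which is much cheaper and uses cleanly disjoint data.

## Statistics

One-sample comparisons of per-subject AUCs against the 0.5 chance level
use sign-flip permutation (exchanging a subject's condition labels flips
the sign of its chance-referenced deviation), statistic = mean deviation,
one-tailed. Two-group comparisons permute pooled group labels (or
sign-flip paired differences), statistic = difference in group means,
10,000 shuffles by default. All permutation p-values use the add-one
estimator (b+1)/(m+1), which can never be anti-conservative. Multiple
testing uses Benjamini–Hochberg step-up FDR. Correlations are Pearson or
Kendall tau-b with two-tailed p-values; normality checks are
Shapiro–Wilk at p < 0.05. The permutation engines are hand-vectorized
(the trivial loops dominate nothing) and are tested against exhaustive
enumeration at small n; FDR, correlations and Shapiro–Wilk are delegated
to statsmodels/scipy and cross-checked against brute-force oracles.

## Desk-scale validation conditions

The package's correctness claims are checked on synthetic data with
known ground truth, at sizes a laptop CPU handles in minutes:

- Null recovery and tag-specificity: 1 subject, 100 epochs/condition,
  20 channels, 1 kHz, 100 (null) or 50 (effect) repetitions.
- Lateness/attendee recovery: 20 subjects sharing one mixing-pattern
  set, 60 epochs/condition at 200 Hz, 16 channels, injected early/late
  gain asymmetries |δ| ∈ [0.8, 1.6] with `assr_amp = 0.025` — chosen so
  the stronger tone half decodes around AUC 0.9–1.0 and the weaker half
  around 0.4–0.7, keeping both halves informative rather than saturated.
- Type-I error: 500 null replicates at 500 shuffles.

The full-size defaults (306 channels, 228 epochs, 1000 repetitions)
remain the package defaults and scale linearly in repetitions.

## Known limitations

- Printed AUC magnitudes from real MEG data cannot be replicated exactly
  by any reimplementation: the original classifier's regularization,
  scaling and fold-scoring conventions are unspecified, and the
  recordings are not redistributable. The package validates method
  properties (chance calibration, tag specificity, parameter recovery)
  instead.
- The Hann-window leakage described above means "off-tag" assertions are
  only clean under the boxcar taper.
- Sliding-window labels use start times; with 1-s windows a window
  "starting early" still contains late content, so peak times compress
  toward the interior for weak temporal asymmetries.
- The simulator's noise is spatially white; real sensor noise is
  correlated across channels, which linear decoders can exploit or
  suffer from. Absolute AUC levels on real data will differ.
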