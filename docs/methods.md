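# Methods

## Scope and data model

The pipeline analyzes one 5-minute multichannel scalp-EEG segment per
subject per time point, at eight labeled peri-treatment time points
(`pre2h, baseline, 1h, 2h, 3h, 4h, 12h, 1d`), on the 19-channel 10–20
montage. Time points are categorical labels in a fixed order, not clock
times. The `baseline` label (second position) is the reference for every
fold change and every Δ statistic; `pre2h` is carried as an ordinary
non-baseline level and acts as a negative control. All signal amplitudes
are in microvolts.

## Preprocessing

Fixed order: resample → notch → high-pass → robust average reference →
1-s edge trim → 5-s non-overlapping epochs.

- **Resampling** to 200 Hz: zero-phase 8th-order Butterworth low-pass at
  0.45 × target rate, then polyphase rational-ratio resampling
  (`scipy.signal.resample_poly`; the ratio is expressed with a
  denominator ≤ 1000, exact for any integer source rate in practice).
- **Notch**: zero-phase second-order IIR notch at 60 Hz, Q = 30.
  **High-pass**: zero-phase 4th-order Butterworth at 1 Hz. Both are
  standard clinical-EEG choices; forward–backward application avoids the
  phase distortion that would bias wPLI.
- **Robust average reference**: channels are flagged bad when the robust
  z-score of their SD (median/MAD across channels, with a floor of 1% of
  the median so near-identical SDs cannot explode the score) exceeds 5,
  or when their maximum absolute correlation with every other channel is
  below 0.4. The reference is the mean of the good channels, subtracted
  from *all* channels; detection is refined over two passes on the
  referenced signal. Bad channels stay in the data — they are only
  excluded from the reference. This is a deliberate simplification of
  full PREP-style cleaning: no RANSAC spatial interpolation, because the
  reference here is a cleaning step, not a reconstruction step, and the
  synthetic cohorts contain no truly dead channels.
- Re-applying the filter chain changes passband content (2.5–45 Hz) by
  < 0.1% RMS; the few-percent full-band change lives entirely in the
  high-pass and notch transition bands.
- For real EDF input an optional amplitude screen drops epochs with any
  |sample| > 500 µV. Segment curation (choosing the artifact-free
  5-minute window, excluding generalized-seizure evolution) is a manual
  step outside the package.

## Spectral features

Multitaper PSD per epoch and channel: DPSS tapers with time–half-bandwidth
product NW = epoch_s × half_bandwidth (default 5 s × 1 Hz = 5) and
2NW − 1 = 9 tapers, mean over tapers of one-sided density-scaled
periodograms. Frequency resolution is 1/epoch_s = 0.2 Hz.

Band edges follow the half-open convention [lo, hi) with β closed at
30 Hz, so δ + θ + α + β exactly partitions broadband 1–30 Hz and the four
relative powers sum to 1. Relative power is computed per epoch (band sum /
broadband sum) and averaged over epochs per channel — the arithmetic mean
of ratios, not the ratio of means, which is robust to slow inter-epoch
power drift. The GLOBAL value is the mean over channels of channel-level
values. The five spectral ratios are computed from the channel-level
aggregated band powers (the broadband normalizer cancels).

## Complexity

Permutation entropy uses embedding order m = 3 and lag τ = 1 (6 ordinal
patterns; a 1000-sample epoch yields 998 motifs, ≈ 160 expected counts
per pattern), normalized by log₂ 3! to [0, 1]. Ties are ranked by order
of occurrence (stable argsort), making the measure deterministic on
quantized data. Per-band values are computed on zero-phase 4th-order
Butterworth band-passed epochs; broadband uses the 1–30 Hz filter.

Spectral entropy is the Shannon entropy of the PSD normalized to a
probability distribution over the in-band bins, divided by log₂ n_bins.
Both entropies are epoch-averaged per channel, then channel-averaged
into GLOBAL rows.

## Connectivity

Cross-spectra come from the same DPSS-tapered FFT coefficients as the
PSD; observations pool epochs × tapers (e.g. 58 × 9 = 522 for a trimmed
5-minute recording), maximizing the count at fixed length. Per frequency
bin

    Coh_xy(f)  = |mean_k S_xy,k| / sqrt(mean_k S_xx,k · mean_k S_yy,k)
    wPLI_xy(f) = |mean_k Im S_xy,k| / mean_k |Im S_xy,k|

and the band value is the mean of the per-bin estimator over in-band bins
(matching common connectivity-toolbox behavior), not the estimator of
band-summed spectra. A bin where every imaginary part is zero contributes
wPLI 0; a bin with a zero auto-spectrum is skipped for coherence. The
debiased-squared wPLI variant is intentionally not used. The GLOBAL value
is the unweighted mean over the C(19,2) = 171 unordered pairs.
Implementation note: the full epochs × tapers × 19 × 19 × freqs tensor of
a 5-minute recording is ≈ 0.5 GB, so `CrossSpectra` stores the tapered
coefficients and materializes one pair at a time.

## Trajectory clustering

Per metric × band, every subject–channel pair contributes the 8-point
fold-change trajectory value_t / max(baseline, 1e−12), z-standardized
across the eight entries (constant rows become all-zero rather than
dividing by zero). Rows with a missing time point or a non-positive
baseline are dropped with a log warning — all shipped metrics are
positive, so drops indicate degenerate inputs. A complete 6-subject
cohort gives 114 rows.

K-means uses k = 5, Euclidean distance, best of 50 seeded random
initializations. A cluster is *distinct* when (a) the Spearman
correlation of its mean profile with the time index 0..7 has p < 0.05
(two-sided t-approximation; p reported as 0 at |ρ| = 1 — the exact
permutation p for n = 8 differs negligibly at these effect sizes),
(b) successive differences of the mean profile from baseline to day 1 do
not oppose the net direction by more than 10% of the profile's range
(strict monotonicity would flag nothing under noise), and (c) sign(ρ)
matches the sign of profile[1d] − profile[baseline]. A silhouette/elbow
sweep over k is available as a diagnostic (`silhouette_elbow_report`);
k stays 5 by default.

## Longitudinal statistics

Δ tables subtract each subject's baseline GLOBAL value, leaving 7 rows
per subject per metric × band. The mixed model is

    Δ ~ 0 + C(timepoint) + (1 | subject),   REML

with *no* global intercept, so each fixed-effect coefficient is directly
that time point's mean change from baseline. Inference is by Wald z; at
6 subjects this is slightly anti-conservative (measured type-I ≈ 0.06 at
nominal 0.05 in the calibration simulation), which the package accepts
rather than adding Satterthwaite degrees of freedom. Benjamini–Hochberg
runs across the 7 time-point contrasts within one metric × band family by
default; a cross-family mode is a caller choice (pass the pooled p list
to `bh_adjust`). Zero subject variance is reported as a singular-fit flag
with results still returned.

Friedman's chi-square uses average ranks without the tie-correction
factor, so an all-tied matrix gives χ² = 0, p = 1 instead of NaN; on
tie-free data it agrees exactly with `scipy.stats.friedmanchisquare`.
Wilcoxon signed-rank post hocs use the exact distribution (n ≤ 25;
normal approximation is invalid at n = 6), drop zero differences
(Wilcoxon's rule), and are BH-corrected across the seven time points.

Weighted Cohen's kappa uses linear ("equal spacing", w = 1 − |i−j|/(k−1))
weights by default, quadratic as an option, with chance agreement from
the product of the raters' marginals. On the packaged 36-cell two-rater
ordinal table (worsened < no-change < improved) the linear and quadratic
kappas are 0.6786 and 0.7483. Perfect agreement is reported as κ = 1
even when a rater used a single category (the ratio is otherwise 0/0);
other degenerate-marginal cases yield NaN.

## Synthetic cohorts

The generator emulates the *statistical structure* the estimators are
sensitive to, not biophysics. Each channel is a sum of:

- pink 1/f^χ background (χ = 1), total RMS 20 µV — a conventional scalp
  magnitude; 60% of background variance is shared zero-lag within scalp
  neighborhoods (frontal L/R, midline, centro-temporal L/R, posterior
  L/R) with a per-subject spatial gain pattern (SD 0.2), so channels are
  spatially correlated like referenced EEG while contributing nothing to
  wPLI;
- band-limited oscillations per neighborhood — band-passed white noise
  (not pure tones, so spectra are broad and entropy non-degenerate) with
  base RMS δ 8, θ 7, α 6, β 4 µV, scaled by the scenario's per-time-point
  amplitude multipliers;
- optional pair couplings: a shared band-limited source (10 µV RMS per
  unit gain) added to both channels, the second copy delayed by
  phase_lag/(2π f_center) via FFT phase rotation — an exact fractional
  delay giving analytic control of the imaginary cross-spectrum;
- optional periodic-discharge-like triphasic transients (20–60–20 ms
  half-sine lobes, 5% timing jitter) and white sensor noise (SD 2 µV).

Native simulation runs at 500 Hz and is pushed through the preprocessing
resampler, exercising the anti-alias path. Determinism: every recording's
generator is spawned from `SeedSequence([seed, subject, timepoint])`;
identical scenarios are bit-identical.

Scenario presets: `responder` couples nine left–right/midline pairs in
theta at π/2 lag with gain 1.0 through baseline declining linearly to 0.6
at day 1 (global theta wPLI falls from ≈ 0.12 to ≈ 0.09);
`non_responder` keeps gains flat; `heterogeneous` mixes declining and
flat couplings with rising delta and falling beta amplitudes. The
amplitude/SNR conventions are choices, not calibrations to any patient
cohort — no amplitude characteristics of real NORSE EEG were available.

What the generator does **not** emulate: artifacts (EMG, eye blinks,
electrode pops), non-stationarity within a segment, seizure evolution,
volume-conduction geometry beyond the neighborhood sharing, or realistic
spatial spectra. Passing tests therefore demonstrate estimator and
pipeline correctness on signals with known ground truth, not clinical
performance on patient data.

## Simulation scales and numerical choices

Tests and the acceptance script run the synthetic cohorts at 20–60 s
segments where only bookkeeping or planted contrasts are measured, and at
the full 5-minute length where epoch counts matter (connectivity noise
floors); the mixed-model calibration uses 200 recovery and 500 null
replicates. The fold-change guard is ε = 1e−12; standardization uses
population SD; K-means ties and the single-observation degenerate
coherence/wPLI (= 1) follow the conventions noted inline. EDF output is
16-bit with per-channel physical scaling (quantization ≤ 1 part in 32767
of the channel peak), 1-s records; reading canonicalizes labels
case-insensitively and maps the legacy temporal labels T3/T4/T5/T6 to
T7/T8/P7/P8.

## Known limitations

- Wald z (not Satterthwaite/Kenward–Roger) inference in the LMM; slight
  anti-conservatism at n = 6 noted above.
- The robust reference is a two-criterion simplification; channels that
  are bad in subtle ways (high-frequency noise with normal variance)
  would pass it.
- Spearman p-values at n = 8 use the t-approximation by default,
  matching mainstream library behavior; `spearman(..., exact=True)`
  enumerates all n! orderings when the exact null is wanted.
- Global connectivity weights all 171 pairs equally; no distance or
  network structure is modeled.
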