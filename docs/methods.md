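# Methods

This note documents the modeling choices, defaults and numerical conventions
behind `vistrf`, and what the synthetic-data validation does and does not
establish about real recordings.

## Encoding model and estimation

The forward model treats each EEG channel as a linear convolution of the
stimulus features with a channel-specific kernel (TRF) over a lag window,
plus a residual. Estimation is ridge regression on the lagged design matrix,
`w = (SᵀS + λI)⁻¹ Sᵀr`, with the penalty applied as a plain identity on the
full lagged covariance — no intercept column, no penalty exemptions, and no
derivative (Tikhonov-smoothness) weighting. The solver is a Cholesky
factorization of the regularized normal equations with a least-squares
fallback for ill-conditioned systems; a singular system at λ = 0 raises an
error advising a positive ridge rather than silently pseudo-inverting.

**Lag window.** Lags are quantized by rounding `t · rate` to the nearest
integer sample; the window spans `round(t_min·rate) .. round(t_max·rate)`
inclusive. The default analysis window is 30–380 ms at 128 Hz (46 lags),
which brackets the P1/N1-type response components of visual speech; a broad
window (−200…500 ms) is available for inspecting component latencies. The
same window is used for every model, including concatenated ones, so model
comparisons are not confounded by window choice.

**Boundary handling.** The lagged design is zero-padded where `t − τ` falls
outside the trial, keeping design and response the same length and exactly
matching the convolutional definition. No rows are trimmed.

**Standardization.** Neither stimulus nor EEG is standardized by default,
staying literal to the normal equations above. Because λ is selected by
cross-validated prediction accuracy rather than fixed a priori, the scale
dependence of the penalty is absorbed by the grid search.

**Cross-validation.** One TRF is fit per training trial; each fold averages
the N−1 single-trial TRFs and predicts the held-out trial. Per-trial
covariances (SᵀS, Sᵀr) are cached, so a λ grid search costs one extra linear
solve per trial per λ, not a re-decomposition of the data. λ is selected at
the session level — one value per model per session, the value maximizing
mean prediction accuracy over trials and the configured electrode subset —
not re-optimized per fold; exact score ties go to the smaller λ. An optional
refinement pass evaluates a constricted grid of ±2 exponent units (step 1)
around the coarse winner; the width is our choice, made once.

**Prediction accuracy.** Pearson r per channel between predicted and
recorded EEG. Channels with zero variance in either signal are flagged NaN
and excluded from all means. Electrode subsets are configuration (channel
names or indices); an 11-site occipital example for a Biosemi-128 montage
ships as `vistrf/data/occipital_biosemi128_example.txt`, but any montage's
list can be supplied.

## Stimulus representations

**Envelope (E).** The audio is decomposed by a bank of 4th-order gammatone
IIR filters (`scipy.signal.gammatone`) at 256 log-spaced center frequencies
between 80 and 3000 Hz; the magnitude of the analytic signal is averaged
over bands and polyphase-resampled to 128 Hz (clipped at zero against
resampling ripple). A gammatone bank is used rather than a level-dependent
gammachirp bank: the chirp correction alters narrowband phase and fine
timing, which is immaterial after averaging 256 bands into one broadband
envelope, and the gammatone design is unambiguous to implement and test.

**Motion (M).** Per consecutive frame pair, block-matching motion vectors
are estimated with Adaptive Rood Pattern Search (ARPS): non-overlapping
16×16 blocks (fully inside the frame only, avoiding padding artifacts),
mean-absolute-difference cost, search range ±7 px. The initial rood arm is
sized by the left neighbor's vector (arm 2 for leftmost blocks), followed by
unit-rood descent until the center wins. Ties go to the smaller displacement
magnitude, then to the earlier-evaluated candidate; on flat frames this
yields (0, 0) everywhere. The motion signal is the sum of vector lengths per
frame transition, with the first sample defined as 0 so the series has one
sample per frame, then linearly interpolated from the frame rate (nominally
30 Hz) to 128 Hz.

*Accuracy of the greedy search.* ARPS is an approximate matcher. On smooth
textured frames under global translation it returns the exhaustive
full-search optimum on > 99% of blocks whose true displacement keeps the
match window inside the frame; the remaining < 1% are stalls in shallow
local minima, almost always leftmost-column blocks, which lack a neighbor
prediction. Blocks whose true match lies outside the frame have no
descent-friendly cost structure, and there the greedy and exhaustive
optima legitimately differ. The validation suite therefore checks block-level
agreement on feasible blocks (≥ 98% over 50 random shifted pairs, shifts up
to ±4 px) plus exact recovery of interior-block displacements, rather than
frame-level identity. `full_search_match` (same cost and tie-break,
exhaustive enumeration) is shipped as the reference baseline.

**Visemes (V).** A phoneme alignment (TSV of label/onset/offset) is collapsed
onto viseme categories via an editable TSV mapping; the bundled default is a
12-category ARPAbet grouping in the style of Auer & Bernstein's visual
phoneme-similarity classes (bilabials /b, p, m/ together, labiodentals
/f, v/ together, alveolar-fricatives /d, t, s, z/ together, five vowel
classes, …). Adjacent same-category intervals are *not* merged, so each
phoneme token remains one viseme occurrence. The indicator is a sustained
binary code over the (shifted) interval — consistent with how categorical
phoneme features are coded in auditory TRF work — with onset-impulse coding
available as a flag.

*Timing shift.* Because viseme timings derive from the acoustic alignment
while visible articulation leads the sound, intervals are translated 150 ms
earlier by default. Both onsets and offsets are shifted (a pure translation,
preserving durations), with onset-only shifting as a flag; onsets are
clipped at zero.

*Sample convention.* Time is in seconds, sample indexing 0-based, intervals
half-open: sample `i` covers `[i/rate, (i+1)/rate)`, and an interval `[a, b)`
activates samples `floor(a·rate) .. floor(b·rate) − 1` (the sample containing
the onset counts; a partially covered offset sample does not). A small
epsilon guards boundaries that are exact in real arithmetic but a few ulps
low in floating point.

**Combinations.** Concatenation of feature columns in the given order (E 1,
M 1, V 12; EV 13, EMV 14); slicing the combined matrix recovers each part
bit-exactly.

## Preprocessing

Band-limiting to 0.3–15 Hz uses a zero-phase forward–backward Butterworth
filter (order 3 per pass): zero-phase filtering is essential because filter
latency would otherwise shift every TRF component. Downsampling to 128 Hz is
anti-aliased polyphase resampling; re-referencing subtracts the
instantaneous channel mean (row sums exactly zero afterwards). All three
operations are linear; the suite checks superposition directly. Bad-channel
handling is assumed upstream.

## Controls and statistics

**Chance level.** For each model, the held-out predictions are re-scored
against 5 recorded trials drawn without replacement from the non-matching
trials (truncated to the shorter length if lengths differ); the
per-prediction averages are pooled across all supplied models and the 95th
percentile of the pool is the threshold. On pure-noise data the threshold
sits within ±0.02 of the analytic null for the record length.

**Viseme-randomization control.** The cross-validation is re-run after
shuffling viseme identities within their exact intervals (per-trial,
per-shuffle seeds derived from one seed). Only category-*specific* response
structure is destroyed by the shuffle; response energy and event timing are
preserved, so a score drop isolates categorical encoding.

**Model comparisons.** Two-tailed paired t-tests (delegated to
`scipy.stats.ttest_rel`, with explicit degenerate handling for zero-variance
differences: identical inputs give t = 0, p = 1; a constant nonzero
difference is flagged with an infinite t). The pipeline pairs per-trial
scores within a session; with several sessions/subjects, per-subject means
should be paired instead — the tidy results table carries what any stats
package needs. Repeated-measures ANOVA across many models is intentionally
left to general statistics software.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, with
a known ground truth. Defaults: 15 trials × 60 s at 128 Hz, 32 channels
(128-channel mode available; 32 keeps desk-scale runs fast), 12 viseme
categories, envelope–motion correlation 0.5, SNR 10 dB.

* **E**: |low-passed (≤ 8 Hz) Gaussian noise|, unit variance — nonnegative
  and slow, like a speech envelope.
* **M**: `α·E′ + √(1−α²)·E₂′` with an independent copy E₂, so the population
  correlation with E equals the configured target (0.5 by default, the
  regime where the envelope is an informative but imperfect proxy for
  motion) while M stays nonnegative.
* **V**: non-overlapping intervals with durations ~ U(60, 300) ms and gaps
  ~ U(0, 100) ms, categories drawn from a fixed three-tier non-uniform
  distribution (weights 4/2/1 for frequent/mid/rare categories) standing in
  for the strong skew of viseme frequencies in natural speech.
* **Ground truth TRF**: per feature, a difference-of-Gaussians kernel with a
  positive peak drawn in 125–140 ms and a negative trough in 210–235 ms
  (P1/N1-like morphology), scaled per channel by a smooth unimodal
  "occipital-like" gain profile. Viseme columns share one kernel shape
  scaled by category-specific amplitudes ~ U(0.2, 1.8) — real viseme TRF
  weights differ by factors of several across categories — so the
  randomization control has categorical structure to destroy. With
  `equal_viseme_amplitudes=True` all categories get identical kernels,
  making the viseme response timing-only: the control's null case.
* **EEG**: the forward convolution of the combined EMV stimulus with the
  true kernel, plus Gaussian noise band-limited to 0.3–15 Hz (so the
  requested SNR is meaningful within the analysis band) scaled per channel
  to the exact sample power ratio.

All randomness flows from one seed through named substreams (stimuli,
ground truth, noise, mismatch draws, shuffles), recorded in the pipeline
manifest; identical seeds reproduce sessions bit-exactly.

**What passing on synthetic data shows — and what it does not.** Recovery
and ordering results demonstrate that the estimator, cross-validation,
λ search and controls are implemented correctly and behave as designed when
the generating model is the fitted model. They do not establish effect
sizes for real EEG: the generator's channels carry independent noise (no
volume conduction), its features are stationary, its viseme timing is exact
rather than alignment-derived, and real prediction accuracies for scalp EEG
are an order of magnitude smaller than at the simulated 10 dB SNR.

## Validation problem sizes

Chosen once for single-core, desk-scale runs and used by both the test
suite and `scripts/acceptance.py`:

* ground-truth recovery: full defaults (15 × 60 s, 32 channels, 10 dB);
  tensor correlation of the averaged per-trial fits with truth ≈ 0.98.
* SNR monotonicity: 8 trials × 30 s, 16 channels, median over 10 seeds of
  held-out accuracy across {20, 10, 0, −10} dB.
* combined-model ordering and the randomization control: 6 trials × 30 s,
  16 channels, 20 seeded sessions (6 shuffles per control run).
* oracle equivalence: 20 random ridge/least-squares instances; 50 shifted
  frame pairs for block matching.

## Known limitations

* Forward (encoding) models only; no backward/stimulus-reconstruction
  models, no banded or per-feature λ.
* One λ per session per model (the cross-validation design); no per-fold
  re-optimization, no nested CV.
* Block matching assumes grayscale frames and translation-only block motion;
  no sub-pixel refinement, no region-of-interest tracking.
* The bundled phoneme→viseme table is a reasonable 12-class ARPAbet grouping,
  not a reproduction of any specific published table; users with a preferred
  inventory should supply their own TSV.
* Forced alignment is consumed, not produced.
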