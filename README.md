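# vistrf

Forward encoding models of **continuous visual speech**: build stimulus
representations of a talking face — the acoustic **envelope (E)**, the video
**motion signal (M)** and categorical **viseme labels (V)** — fit lagged
ridge-regression **temporal response functions (TRFs)** to multichannel EEG,
and compare models by leave-one-out cross-validated EEG prediction, with
chance-level and viseme-randomization controls.

The package is aimed at researchers studying neural entrainment to natural,
continuous speech (silent lipreading in particular): it provides the full
analysis path from raw media (WAV audio, grayscale video frames, phoneme
alignments) to per-model prediction accuracies, plus a synthetic-data
generator with known ground-truth TRFs so that every stage of the pipeline
can be validated by parameter recovery.

## The model

The EEG at channel *n* is modeled as a convolution of the stimulus feature
vector *s(t)* with an unknown channel-specific kernel *w*(τ, *n*) — the TRF —
over a window of stimulus-to-response lags [*T*min, *T*max] (30–380 ms by
default):

    r(t, n) = Σ_τ  w(τ, n) · s(t − τ)  +  ε(t, n)

Stacking lagged copies of *s* into a design matrix *S* turns estimation into
ridge regression:

    w = (SᵀS + λI)⁻¹ Sᵀr

λ is chosen per recording session by a grid search (2⁻²⁰ … 2²⁰) maximizing
leave-one-out cross-validated prediction accuracy: each fold fits one TRF per
training trial, averages them, predicts the held-out trial's EEG, and scores
the prediction with Pearson's *r* per channel (optionally averaged over an
electrode subset, e.g. occipital sites).

Stimulus features at the EEG rate (128 Hz):

* **E** — mean of narrowband Hilbert envelopes over a gammatone filterbank
  (256 log-spaced bands, 80–3000 Hz) of the speech audio; a proxy for
  speech-related mouth motion during silent video.
* **M** — per frame pair, the sum of Euclidean lengths of block-matching
  motion vectors (Adaptive Rood Pattern Search), upsampled from the frame
  rate to 128 Hz.
* **V** — a binary time × 12 indicator of viseme occupancy obtained by
  collapsing a phoneme alignment onto visually-indistinguishable phoneme
  classes (e.g. /b, p, m/), shifted 150 ms earlier to compensate for visible
  articulation leading the acoustics.
* Concatenations **EV, MV, EM, EMV** combine the columns of their parts.

Two controls separate genuine feature encoding from confounds: an empirical
**chance level** (95th percentile of prediction accuracy against mismatched
EEG trials) and a **viseme-randomization control** (shuffling viseme
identities while preserving their exact time intervals — a drop in accuracy
shows the model tracks *which* viseme occurs, not mere event timing).

## Worked example

Run the full pipeline on a small simulated session (5 trials × 20 s, 8
channels, 10 dB SNR):

```sh
cat > demo.cfg <<'CFG'
n_trials = 5
duration = 20
n_channels = 8
snr_db = 10
grid = -8:8:4
seed = 0
CFG
vistrf pipeline --config demo.cfg --out demo_out
```

which prints (a few seconds on one core):

```
model   mean_r  lambda
    E 0.763875     1.0
    M 0.755302    16.0
    V 0.246299    16.0
   EV 0.824910    16.0
   MV 0.816138    16.0
   EM 0.888212   256.0
  EMV 0.949730    16.0
chance threshold: 0.063277
```

Each row is one encoding model: `mean_r` is its leave-one-out cross-validated
prediction accuracy (mean Pearson *r* between predicted and recorded EEG over
trials and channels) at the grid-selected ridge parameter `lambda`. All
models clear the mismatched-trial chance threshold; the combined models beat
their components (EMV highest), which is the expected signature when the EEG
genuinely carries independent envelope, motion and viseme contributions — as
this simulated session does by construction. `demo_out/` also contains the
tidy per-trial, per-channel results table, pairwise model comparisons
(paired t-tests across trials), and a JSON manifest of every setting and
seed substream.

The same stages are available as library calls (`vistrf.compute_envelope`,
`vistrf.fit_trf`, `vistrf.loo_predict`, `vistrf.randomization_control`, ...)
and as individual CLI commands (`vistrf features envelope|motion|visemes`,
`vistrf fit`, `vistrf crossval`, `vistrf chance`, `vistrf control`,
`vistrf compare`, `vistrf simulate`).

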