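# Methods

This note documents the models and numerical choices behind `sleeptf`:
what each stage of the pipeline computes, which parameters matter, what
the synthetic data generator does and does not emulate, and where the
design was genuinely open.

## 1. Signal model and preprocessing

The unit of analysis is the AASM sleep epoch: 30 s of single-channel EEG,
one stage label from {W, N1, N2, N3, REM} (encoded 0–4 throughout). All
inputs are brought to a common 256 Hz rate, so an epoch is a vector of
7680 samples.

Pipeline order is fixed: **resample → bandpass → segment**.

* *Resampling* is polyphase rational resampling (`scipy.signal.
  resample_poly`), alias-safe and duration-preserving to within a sample.
* *Bandpass* is a 4th-order Butterworth, 0.3–35 Hz, applied
  forward–backward (`sosfiltfilt`) so the group delay is exactly zero.
  The effective magnitude response is the square of the single-pass
  response; at 50 Hz the designed squared gain is ≈0.03 and the measured
  steady-state attenuation matches it to <1 %.
* *Segmentation* uses 0-based half-open sample spans [i·7680, (i+1)·7680);
  a trailing partial epoch is dropped with a warning. Unscored epochs
  (label −1) are dropped by default; a strict mode raises instead.

Filtering and resampling do not commute exactly: Butterworth designs at
different rates differ by bilinear-transform frequency warping, and the
polyphase FIR adds passband ripple. On in-band tones the two orders agree
to ~10⁻³ RMS (worst near the upper band edge), not machine precision;
the pipeline's fixed order makes the choice irrelevant downstream.

EDF I/O is a minimal reader/writer for plain continuous 16-bit EDF
(one signal, physical range ±1000 µV, so the quantization step is
2000/65535 ≈ 0.031 µV). Truncated files raise I/O errors rather than
silently shortening the record.

## 2. Time–frequency imaging

### FSST

The short-time Fourier transform uses a Gaussian window of scale
γ_g = 0.25 s sampled on 257 points (~1 s), hop 32 samples, 512-point FFT,
with each frame demodulated at the window center. The instantaneous
frequency map is estimated with the derivative-window identity

  ω̂(η, t) = f_η − Im( V_{g′}(η,t) / V(η,t) ) / 2π ,

valid where |V| exceeds a masking threshold (default 10⁻⁶ of the grid
maximum). For a pure tone this estimator is exact up to window-truncation
error: within the mainlobe the error is <0.1 Hz; sidelobe bins (|V| a few
percent of the peak) carry unreliable estimates but negligible energy.

The window bandwidth convention is the standard Gaussian half-power
bandwidth Δ = √(2 ln 2)/γ_g, giving the resolvability condition
d = 2Δ (≈ 9.4 Hz at the default γ_g): two components whose instantaneous
frequencies stay at least d apart reassign to distinct ridges.
`ModeModel` builds AM–FM test signals that honor (or deliberately
violate) this separation.

Synchrosqueezing reassigns each unmasked coefficient along frequency only
(time localization, hence causality, is untouched) to the bin nearest
ω̂, scaled by 1/g(0). The Dirac integral is discretized by nearest-bin
accumulation on the STFT's own frequency grid. Two quantities ride the
same transport and are conserved per frame *exactly* (they are regrouped
sums): the complex coefficients, and the |V|² energy mass accumulated in
the grid's `energy` plane. Note that column sums of |T|² are **not**
conserved — coherent bins that merge add in amplitude, which is precisely
why the transform concentrates ridges (its normalized spectral entropy
drops relative to the STFT on every separated AM–FM test signal).

### CWT

The scalogram uses the exactly analytic generalized Morse wavelet,
frequency-domain form a·ω^β·e^(−ω^γ) for ω>0, with symmetry γ=3 and
time-bandwidth β=20, normalized to peak value 2 so a unit-amplitude real
tone produces ridge magnitude ≈1. Scales form a geometric grid at 12
voices per octave whose center frequencies f_c = ω_p/(2πs)·fs (with peak
frequency ω_p=(β/γ)^(1/γ)) must cover the 0.3–35 Hz scoring band
(default grid tops out near 38 Hz so the 35 Hz edge is interior).
Convolution is circular via FFT; translation covariance is exact and
tone-to-scale mapping is within one voice across the band.

### Rendering

Grid → image: crop rows to 0.3–35 Hz, magnitude, log1p compression
(EEG TF magnitudes span orders of magnitude; raw min–max would
saturate), per-image min–max to [0,1], bilinear resize to 224×224
(anti-aliased), highest frequency on top, and channel replication to
224×224×3 (a named matplotlib colormap is available but off by default
for determinism). An all-constant grid renders to the all-zero image
with a warning. Because log1p is not affine, rendering is idempotent only
with log compression disabled; the normalization/resize core is.

## 3. Classifiers

Both variants consume 224×224×3 images in [0,1] and end in a 5-way
softmax. They are implemented in numpy with hand-written backprop
(verified against central differences end to end).

* **cnn**: backbone → dropout 0.5 → fully connected → softmax.
* **cnn_rnn**: backbone → sequence unfolding (each of the W_f feature-map
  columns becomes one vector of length H_f·C_f, frequency-major then
  channel — the image's time axis is the sequence axis) → BiLSTM →
  dropout 0.3 → BiLSTM → dropout 0.3 → softmax on the sequence summary.

The LSTM recurrence is the standard gated update (sigmoid gates, tanh
cell/output activations); `lstm_step` implements it literally per gate
and the fused training layer is tested to reproduce it to 1e-12. A
BiLSTM runs a second parameter set over the reversed sequence and
concatenates outputs position-wise. The sequence summary feeding the
softmax is the *final state of each direction* (forward state at the last
step, backward state at its own last step, i.e. position 0) — the
standard sequence-to-one reduction; summarizing at a single position was
the main open choice and is isolated in one place.

The default backbone ("compact") is four conv blocks
(7×7/stride-4 conv → 3×3 convs with 2×2 max-pools) ending in a 7×7×64
map, so the RNN sees a 7-step sequence; it trains from scratch at desk
scale while honoring the 224×224×3 input contract. A
"pretrained-adapter" backbone slot exists for an externally supplied
GoogLeNet-class feature extractor cut at its last pooling layer; no
weights ship with the package, and requesting it without weights raises
an explicit error pointing back to the compact backbone. The backbone
can be frozen (then only RNN/head parameters change — enforced by a
parameter-hash test) or fine-tuned at a reduced learning rate (default).

Within-epoch sequence semantics: the recurrence ranges over the feature
columns of a single epoch's image, keeping the classifier strictly
one-to-one (one epoch in, one label out). Sequences over *successive
epochs* would be the alternative reading; it is deliberately not
implemented.

## 4. Training and evaluation

* Split: epoch-level random 90/10 (|train| = round(0.9 N)), optional
  stratification (largest-remainder per-class rounding, within one epoch
  of the target fraction). Epoch-level splitting mirrors the evaluation
  protocol this design follows; subject-wise splitting is stricter and
  can be had by splitting before pooling recordings.
* Oversampling: random duplication with replacement until every class
  matches the majority count — training portions only, never evaluation
  data (enforced by tests); balanced inputs are returned unchanged.
* Optimizer: SGD with momentum 0.9, batch 32. Library defaults are
  lr 10⁻³ (head) / 10⁻⁴ (backbone), geared to fine-tuning a transferred
  backbone; the from-scratch desk-scale runs in the tests and the
  acceptance script use lr 0.02 for both groups, which trains the compact
  network to convergence on the synthetic task in a few passes.
  Non-finite loss aborts with a diagnostic.
* 20-fold CV: pairwise disjoint, exhaustive folds with sizes differing by
  ≤1; oversampling is applied inside each fold's training portion only.
  The summary reports per-class mean and **population** standard
  deviation (the flavor is not specified by the protocol; population was
  chosen and is documented here), plus the unweighted across-class
  average of each metric column.
* Metrics: one-versus-all TP/FP/TN/FN per stage; Sn, Pr, F1, Sp, ACC in
  percent; overall ACC is the confusion-matrix trace over N; MF1/Sn/Sp
  are unweighted 5-class means. Zero-denominator policy: an undefined
  Pr/F1 (no predictions for a class) is NaN in machine-readable output,
  counts as 0 in macro averages, and logs a warning. Reports print one
  decimal; machine-readable output keeps full precision.

## 5. The synthetic world

The generator exists because the clinical recordings this pipeline was
designed around are access-restricted. It reproduces the *statistical
structure the pipeline relies on*, not sleep physiology:

* **Hypnogram**: a first-order Markov chain over 30-s epochs starting in
  Wake, with default transition weights giving the cyclic
  W → N1 → N2 ⇄ N3 → REM → W progression. An optional
  proportion-matching step (iterative column reweighting until the
  stationary distribution hits a target) reproduces any marginal stage
  distribution; the default target is the pooled distribution of two
  clinical cohorts (W 24.6 %, N1 15.1 %, N2 42.5 %, N3 7.2 %, REM
  10.7 %, from 72,496 scored epochs). Default stage bouts are a few
  epochs long — shorter than physiological bouts — a deliberate
  trade-off so that night-scale simulations (≈20,000 epochs) match the
  target marginals within Monte-Carlo error of ±0.02. Consequently,
  full 90–120 min cycle durations are *not* reproduced at the default
  settings; raising the diagonal dwell weights restores long cycles at
  the cost of slower mixing.
* **Waveforms** (artifact-defined; no claim of physiological fidelity
  beyond band structure): each stage is a drifting narrowband oscillation
  in its textbook band — alpha 8–12 Hz (W), theta 4–7 Hz (N1, N2), delta
  0.5–2 Hz at 75–150 µV (N3) — plus stage events: N2 adds ~3 spindle
  bursts (11–16 Hz, ~1 s) and ~1 biphasic K-complex (~120 µV pp) per
  epoch; REM is low-amplitude mixed activity with 2–4 Hz sawtooth-like
  (triangular) trains. Amplitudes follow textbook peak-to-peak ranges
  (W/N1/REM 10–40 µV, N2 40–60 µV). Background is 1/f colored noise at
  −10 dB total power relative to the stage rhythm. All generation is
  reproducible from (spec, seed), bitwise.

What a green end-to-end test establishes: the imaging, training,
oversampling and evaluation machinery recovers stage structure whose
discriminative information lives in time-frequency signatures, under
realistic class imbalance. What it does **not** establish: clinical
accuracy. The synthetic stages are more separable than real sleep EEG —
no artifacts, no subject heterogeneity, no ambiguous transitions — so
held-out performance near 100 % is expected and says nothing about
performance on real recordings. One consequence shows up in the
oversampling comparison: the minority stage that *suffers* without
oversampling is N1 (it shares its theta band with N2 and is distinguished
only by the absence of spindles/K-complexes), while N3's high-amplitude
delta is so distinctive that its sensitivity sits at ceiling with or
without balancing. The oversampling benefit is therefore asserted on the
aggregate minority-stage (N1/N3/REM) sensitivity, dominated by N1 — the
same qualitative pattern reported for the real data, where N1 showed the
largest oversampling gain.

## 6. Desk-scale configuration

The library defaults keep the full-size architecture (64-channel final
feature map, 128/128 BiLSTM). The acceptance tests and script use a
narrowed configuration — backbone widths (8, 16, 32, 32), BiLSTM 64/64,
3–4 training passes — chosen *only* to fit a single-CPU time budget
(~6 ms/sample per training step); on the synthetic task the narrow and
full configurations reach the same ceiling. The 2,000-epoch end-to-end
test runs in ~4 minutes; the full test suite in about six.

## 7. Known limitations

* The EDF writer pads the final data record with zeros when the signal
  length is not a whole number of records; epoch bookkeeping comes from
  the label CSV, not the EDF tail.
* The FSST instantaneous-frequency map is unreliable in window-sidelobe
  regions (negligible energy, but visible if the mask threshold is set
  very low).
* Neural-network training is single-process numpy: deterministic for a
  fixed BLAS configuration, but ~10⁴× slower than a GPU framework; the
  package is a reference implementation, not a production trainer.
* No artifact rejection, re-referencing, notch filtering, EOG/EMG
  channels, or inter-epoch context (many-to-one/many-to-many schemes are
  out of scope by design).
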