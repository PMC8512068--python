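# Methods

This note records the modeling choices behind `fogsense`, the parameters
that matter, and what the synthetic benchmark does and does not establish.

## Problem and labels

Recordings are tri-axial accelerometer streams from ankle (A), leg (L) and
trunk (T) sensors at 64 Hz with per-sample annotations: 0 = not part of the
experiment, 1 = experiment without freezing, 2 = freezing of gait (FOG).
Annotation-0 samples are removed before any analysis; by default the
surviving stretches are kept as separate segments so that no analysis
window straddles a temporal gap (`combine_magnitude(split_at_gaps=True)`).

Axis fusion takes the euclidean magnitude per sensor. All downstream
features are computed on this magnitude stream; the pipeline is therefore
insensitive to sensor orientation (magnitude is rotation-invariant) and to
absolute acceleration units (classification-relevant features are either
unit-covariant or scale-free).

Windows are non-overlapping, `w·fs` samples, `w` ∈ 1–4 s with default 2 s.
Class rule: a window containing **any** FOG-annotated sample is FOG — the
conservative choice for a safety application, configurable in principle to
majority voting but not needed here. The single window immediately
preceding each FOG run, if currently NonFOG, becomes PreFOG; FOG labels are
never overwritten, so back-to-back episodes keep their observed state.
PreFOG is fixed at exactly one window: with `w = 2 s` a positive PreFOG
prediction is a 2-second warning. The trailing remainder of each segment
(< 1 window) is discarded.

## Class balancing

PreFOG contributes one window per episode and is therefore rare. SMOTE
oversamples each minority class to the NonFOG count: a synthetic row is
`x + u·(x′ − x)` with `u ~ U(0,1)` and `x′` one of the `k = 5` nearest
same-class neighbors (clipped to class size − 1). Balancing operates on
**flattened raw windows**, and every representation (features, images) is
derived from the balanced windows afterwards, so all modalities of a
synthetic sample describe the same signal. The default placement is inside
each training fold — the test fold never sees synthetic data. A
`replication` policy that balances before splitting exists for parity with
protocols that order the steps that way; it is more optimistic because
interpolated neighbors of test rows can appear in training.

## Features (27 per window)

Order statistics and moments (min, max, range, mean, median, mode, 10%
trimmed mean, std, variance, RMS, mean |x|, median absolute deviation,
25th/75th percentile, IQR), magnitude-area and crossing measures
(normalized signal magnitude area Σ|x|/n, mean crossing rate), shape
moments (moment skewness, non-excess kurtosis), and spectral measures on a
rectangular-window periodogram `P[k] = |X_k|²/n`: peak |DFT|/n, Shannon
entropy of the DC-excluded normalized periodogram (natural log), energy
Σ|X_k|²/n, peak frequency (DC excluded), freeze-band power (3–8 Hz),
locomotion-band power (0.5–3 Hz), their ratio (freeze index) and their sum
(band power). Band power is the bin sum of `P` over the band divided by
`fs`. Conventions for degenerate inputs: a constant window has mode = its
value, zero spread statistics, zero crossing rate, entropy 0 and an
infinite freeze index (flagged by a warning; clamped to 1e6 when the
vector feeds a network).

The descriptor catalogue lists two names — normalized signal magnitude
area and signal vector magnitude — that coincide on a fused magnitude
stream (both reduce to mean |x| once the axes are combined upstream). The
default vector keeps `norm_sma` and drops the redundant alias, giving
exactly 27 values; `keep_svm=True` swaps the name.

## Image encodings

All four encodings render to 3×H×W (default 128×128, reduced profile
32×32) through a fixed perceptually uniform colormap (viridis) after
min-max scaling of the matrix; downscaling smooths first (anti-aliasing)
so fine texture such as recurrence lines maps to local density instead of
sampling noise. Network-side normalization divides each channel by 255 and
then by its mean, leaving non-zero channels with mean exactly 1 (an
all-zero channel is left untouched with a warning). The printed form of
that normalization formula is typographically ambiguous in places this
procedure is usually described; the implementation follows the two-step
prose reading (scale to [0,1], then divide by the mean) — the literal
one-step reading is not offered because it produces negative images.

* **Recurrence plot** — `R(i,j) = 1 ⇔ |x(i) − x(j)| ≤ ε`. ε policies:
  fixed value, fraction of signal range, or percentile of pairwise
  distances (default: 10th percentile — scale-free, standard recurrence
  practice).
* **STFT** — Hann taper, segment `fs/4` samples, 50% overlap (≥ 8 frames
  per 2-s window at 64 Hz); only frames fully inside the window are kept
  so no slice mixes signal with zero padding.
* **Haar DWT** — one orthonormal level (approximation + detail), drawn as
  two stacked heatmap bands. Heatmaps rather than rasterized line plots:
  resolution-independent and deterministic.
* **PWVD** — Wigner-Ville kernel `z(n+k)·z*(n−k)` on the analytic signal,
  an odd Hann lag taper of length ⌊n/4⌋ (oddified) supplying the frequency
  smoothing, FFT over the lag. Real-valued, one time slice per sample,
  quadratic in amplitude.

## Classifiers

Implemented on a small numpy engine (`fogsense._nn`) with exact gradients
(verified against numerical differentiation to ~1e-7 relative error).

* **CNN** (image modalities): 4 × [Conv 4×4 "same" → LeakyReLU(0.3) →
  MaxPool 2×2 → Dropout 0.25] with filter counts 64/32/16/8, then flatten
  → Dense 100 → Dense 50 (LeakyReLU, dropout 0.2 each) → softmax-3.
  RMSProp, learning rate 1e-4. Inputs must survive four poolings (≥ 16×16).
* **BiLSTM** (raw window and feature vector read as length-`l` sequences of
  one value): 4 stacked bidirectional layers, hidden width `3·l` per
  direction, tanh cell activations; all layers but the last return
  sequences, the last emits its two final states into a softmax-3 head.
  Adam, learning rate 1e-4.

Training: stratified 80/20 train/validation split, minibatches (default
32), up to 500 epochs, early stopping after 50 epochs without strict
improvement of validation accuracy, best-epoch weights restored. Weight
init is uniform ±1/√fan-in from a seeded generator; dropout masks and
shuffling draw from the same generator, so runs are bit-reproducible per
seed.

**Reduced profile** (CPU-scale experiments; always selected explicitly):
32×32 images, filters [16,8,4,2], ≤30 epochs; BiLSTMs shrink to 2 layers
of hidden width 24. The optimizer compensates the short epoch budget:
learning rate 3e-3 with batch 8 for the CNN (the four-pool bottleneck on
32×32 leaves an 8-unit flatten, and RMSProp at the full-scale rate cannot
converge in 30 epochs), 1e-3 with batch 32 for the BiLSTM. All inputs —
image tensors included — are standardized per component with training-set
statistics before entering a network.

## Ensembles

The six constituents (4 CNNs + 2 BiLSTMs; any ≥ 2 subset is accepted)
combine three ways. *Stacked*: constituent softmax outputs concatenated
(6×3 = 18) into a trainable Dense-10-ReLU → Dense-3-softmax head, trained
with Adam 1e-4 on the same training partition as the constituents (frozen).
*Average*: elementwise mean of probability rows — a pure function.
*Majority*: hard vote over argmax labels; ties break to the tied class with
the largest summed constituent probability, then to the lowest class index.
Stacking on near-perfectly-fitting constituents can underperform the
simpler rules (the head sees little disagreement to learn from); the
majority vote is the recommended default.

## Evaluation

Metrics derive from the K×K confusion matrix: accuracy = trace/total;
one-vs-rest precision, recall, specificity and Fβ per class (β = 1 by
default, exposed); weighted averages use true-class supports, which makes
weighted recall identically equal to accuracy. Zero-denominator
conventions, flagged in the report: precision of a never-predicted class
is 0, recall of an absent class is 0, and R_K with degenerate marginals is
0. Cross validation is shuffled stratified K-fold (K = 5 default; the
driver takes any K each class can support) with a fresh model per fold and
mean ± sd aggregation; per-model runtime covers training plus testing,
excluding representation extraction.

## Synthetic benchmark

The generator produces what the pipeline assumes about real data, not a
biomechanical gait model. The fused magnitude is a unit gravity offset
plus: walking — three tones drawn from 0.5–3 Hz (total amplitude 0.4) plus
Gaussian noise (sd 0.05); FOG — walking content attenuated to 0.3 of its
amplitude plus two dominant tones from 3–8 Hz (amplitude 0.4); PreFOG (the
stretch one window long before each onset) — walking attenuated to 0.35
with a weak freeze-band component (amplitude 0.25) building up. The PreFOG
design mirrors two observations about real transitions: step peaks shrink
before an onset, and freeze-band trembling emerges; the amplitudes were
fixed by a separability probe (PreFOG must be linearly separable in every
encoding, including the scale-free recurrence plot, for downstream model
tests to be meaningful) and are not revisited per experiment. Episode
durations are normal with mean 7.3 s, sd 6.7 s, truncated to 0.5–40.5 s —
the published clinical statistics for the benchmark corpus; walking
stretches are uniform 6–14 s. Axis channels are a fixed per-sensor unit
direction times the magnitude, so fusion recovers the designed spectrum
exactly; sensors differ by scale (A 1.0, L 0.9, T 0.7) and independent
tone draws. With `align_to` set (as `make_balanced_windowset` does),
episode bounds snap to the window grid and the pipeline's window labels
provably coincide with the generator's ground truth.

What passing tests show: the pipeline recovers classes whose spectral and
amplitude structure matches its assumptions, end to end, including under
SMOTE and cross validation. What they do not show: performance on real
recordings — real FOG varies across patients and episodes, transitions
have variable duration, sensors carry artifacts, and class boundaries are
annotated by humans; none of that variability is emulated.

## Scales used in the shipped checks

The test suite trains at the reduced profile on a simulated recording with
20 FOG episodes (~250 windows at w = 2 s), 3 stratified folds, four
constituents (RP and DWT CNNs, feature and raw BiLSTMs) plus the majority
ensemble, asserting macro accuracy (mean per-class recall, fold-averaged)
above 0.8 for every model — a level at which all three classes, including
the 20-window PreFOG minority, must be recovered. These sizes are the
package's own benchmark conditions; larger runs use the `full` profile
through `fogsense run`.

## Known limitations

* The numpy engine is single-threaded and CPU-bound; full-profile training
  on a real corpus is possible but slow, and no GPU path exists.
* SMOTE interpolates raw windows linearly; for strongly non-linear
  manifolds (real tremor) synthetic windows may fall off-manifold.
* The stacked ensemble head is trained on constituent outputs over the
  constituents' own training partition, which underestimates constituent
  error; a held-out stacking partition would be a straightforward
  extension.
* PreFOG duration is fixed at one window; variable-duration transition
  estimation is out of scope.
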