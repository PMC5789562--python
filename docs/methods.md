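# Methods

## Signal model and preprocessing

The detector never sees the raw trace directly. Two derived signals are
computed and kept index-aligned with their timebases by defining the first
element of every differenced sequence as 0:

* difference signal `s_d[n] = s_r[n] − s_r[n−1]` (raw timebase, mV per
  sample step);
* averaged-difference signal: non-overlapping block means of `N_i`
  consecutive samples (trailing partial block discarded), then the same
  first-order difference, on a timebase decimated by `N_i`.

`N_i = 5` is the default: with 360 Hz input a 56-sample window then spans
0.78 s on the averaged timebase and 0.16 s on the raw timebase, i.e. one
whole beat and one QRS complex respectively. `N_i` is exposed as a
parameter everywhere it matters. No filtering, baseline correction or
normalisation is applied; differencing already removes the DC level, and
the network is expected to absorb the rest.

## Segmentation and labelling

Detection points enumerate the averaged timebase. The raw-timebase sample
aligned with averaged index `c` is `c·N_i + ⌊N_i/2⌋` (the middle of the
averaged block). Each point yields a window pair: 22 samples before the
point and 33 after it on both signals (56 samples each). Points whose
windows would cross a record edge are skipped, so roughly the first and
last second of a record are unscanned — the unavoidable warm-up of any
windowed detector.

Training labels (four classes: Q, R, S, non-QRS):

* **R** if the centre lies within ±1 averaged sample (±`N_i` raw samples,
  ≈14 ms at the defaults) of a reference R apex;
* **Q**/**S** if within ±2 raw samples of the beat's Q/S landmark. Beat
  databases typically annotate only the R fiducial, so missing landmarks
  are located as the raw-signal minimum within 0.06 s before/after R;
* **non-QRS** if farther than 0.2 s from every R apex;
* otherwise the point falls in an ambiguous band and is excluded from
  training entirely.

Balanced training sets are drawn uniformly (seeded) from the eligible
centres of each class.

## Network

Object branch: conv(k=5, 5 maps, ReLU) → mean-pool(2) → conv(k=5, 5 maps,
ReLU) → mean-pool(2); lengths 56 → 52 → 26 → 22 → 11, flattened to 55
features. Part branch: one conv/pool stage, 56 → 52 → 26, flattened to
130. Concatenation (object first) → dense 20 ReLU → dense 4 softmax. The
shape arithmetic is recomputed and asserted when a `NetworkSpec` is
constructed, so any deviation from the 185-feature audit fails immediately.

Numerical conventions, fixed for reproducibility:

* "convolution" is valid (no-padding) cross-correlation without kernel
  flip; with learned kernels the flipped convention is an equivalent
  re-parameterisation;
* the second object-level conv layer is fully connected across its five
  input maps (each output map sums correlations over all input maps);
* mean pooling discards a trailing partial block; its gradient broadcasts
  `1/factor` into each pooled block and 0 into a discarded tail;
* ReLU subgradient at 0 is 0;
* softmax is computed with max-shift for stability; outputs are strictly
  positive and sum to 1.

## Training

The objective is the summed squared error between the softmax posterior and
the one-hot target. This is an unusual pairing — the gradient must run
through the full softmax Jacobian `∂y_j/∂z_k = y_j(δ_jk − y_k)` rather than
the `y − t` shortcut — and is implemented exactly as stated; cross-entropy
is available behind `TrainConfig(objective="cross_entropy")` for
comparison. Gradients for every tensor are derived by hand and verified
against central finite differences (h = 1e-5; observed agreement ~1e-7
relative, asserted < 1e-4).

SGD with η₀ = 0.005 decayed multiplicatively, η_t = η₀·(1 − 10⁻⁶)^t per
mini-batch iteration. The decay is read as multiplicative ("reduce by
0.0001 %") because an absolute decrement of the same size would drive the
rate to zero and below within 10⁶ iterations. Defaults chosen where the
regimen was open: batch size 16, at most 200 epochs, He-style Gaussian
initialisation (sd √(2/fan_in), zero biases, seeded), a stratified 10 %
validation split with early stopping (patience 20), best-validation
parameters returned. Mini-batch gradients are averaged over the batch.

## Detection policy

The trained network is slid at a stride of one averaged sample.
Contiguous runs where the R posterior exceeds 0.5 become candidate events;
each event sits at the run's maximal-posterior centre, mapped to the raw
timebase. Events closer than a 0.2 s refractory period (the physiological
minimum RR interval) keep only the higher-confidence member. Each
surviving event then snaps to the maximal-|amplitude| raw sample within
±0.05 s, with amplitude ties broken towards the original index so the
refinement is idempotent and a flat signal is left untouched. Q and S
posteriors are exposed in the scan stream for downstream wave delineation
but do not form events: beat-level scoring counts R events only.

## Evaluation

Greedy one-to-one nearest-neighbour matching within 0.15 s (the standard
beat-matching tolerance); candidate pairs are accepted in order of
increasing distance with a leftmost tie-break. With beats separated by more
than twice the tolerance — always true under the 0.2 s refractory — this
equals the optimal assignment, which the tests verify against an exhaustive
assignment oracle. Metrics are kept at full precision and rounded half-up
to two decimals only at report time; pooled "overall" rows are computed
from summed TP/FP/FN counts, never by averaging percentages. Both
conventions were confirmed self-consistent against the published per-record
benchmark tables embedded in `qrsnet.reference_tables`.

## Synthetic data

Each beat is a superposition of five Gaussians; defaults (amplitude mV /
sigma s / offset from R s): P +0.15/0.030/−0.20, Q −0.15/0.012/−0.04,
R +1.00/0.020/0.00, S −0.20/0.012/+0.04, T +0.30/0.070/+0.30 —
a qualitatively realistic clean MLII beat. RR intervals jitter
lognormally around 60/mean_hr (default fractional sd 0.05), clipped to
[0.3 s, 2.0 s]; beats start half an RR into the record and stop 0.45 s
before its end so every wave fits. Optional sinusoidal baseline wander
(default off) and white Gaussian noise at a requested SNR complete the
model. The SNR reference is the mean square of the mean-removed whole
record — a convention this package fixes explicitly, since "SNR in dB"
alone does not determine one. One global seed is split by purpose (RR
schedule vs noise) via hashed seed sequences, so noise realisations can
vary while the beat sequence stays fixed; every output is a pure function
of (config, seed).

What the generator does **not** emulate: pathological morphologies
(ectopy, bundle-branch blocks, atrial fibrillation), electrode motion or
muscle artifact, amplitude drift, multi-lead structure. Passing the
synthetic end-to-end checks therefore demonstrates that the pipeline is
implemented correctly and can learn and recover stereotyped beats under
heavy additive white noise — it does not certify clinical-grade
performance on real arrhythmia databases.

## Problem sizes used in the checks

The end-to-end checks train on a balanced corpus built from 400 beats
(1600 window pairs) generated at 60 bpm over 60 s records, evaluate on ten
held-out 60 s records (~595 beats), and sweep SNR ∈ {40, 20, 10, 5} dB
with five noise seeds per record. On the stereotyped synthetic morphology
the detector stays at 100 % Sen/PPR down to 5 dB, so the required
monotone degradation holds as an all-equal chain; noisier, less
stereotyped data would be needed to surface a graded decline.

## Known limitations

* The four-class head is trained, but only the R posterior drives event
  formation; Q/S delineation quality is untested beyond label accuracy.
* Greedy matching can differ from optimal assignment if a prediction
  stream ever violated the refractory constraint (it cannot, by
  construction of `decide`).
* WFDB import requires the optional `wfdb` dependency and selects a single
  named channel; multi-lead fusion is out of scope.
* The squared-error-on-softmax objective trains noticeably more slowly
  than cross-entropy; the default 200-epoch budget is sized for it.
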