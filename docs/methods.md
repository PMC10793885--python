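# Methods

This note records the models, defaults and design choices behind
`cxrfuse`, and what the desk-scale experiments do and do not establish.

## Task and scoring

The task is binary: label 1 ("Abnormal") vs 0 ("No finding"); a model's
score is the softmax probability of the abnormal class.  The decision
rule is `score >= threshold` (inclusive, so the scan over unique
validation scores is exhaustive), and the operating threshold is chosen
on the model's own validation split by maximizing the F-score.
Candidate thresholds are exactly the sorted unique validation scores —
any other value duplicates a confusion matrix — with ties broken toward
the smallest threshold.

Reported metrics: balanced accuracy, precision, recall, F, MCC, and
AUPRC.  AUPRC is the non-interpolated average precision (sum over recall
steps of precision), a never-optimistic estimator; trapezoidal
interpolation would differ in the third decimal on small tests.
Zero-denominator metrics report 0 with a logged warning rather than
raising, because degenerate confusion matrices are routine in early
training epochs.

## Confidence intervals and the Z-test

The default MCC interval is the proportion-style normal form

    mcc ± 1.96 · sqrt(mcc·(1−mcc)/n),   n = evaluation-set size,

clipped to [−1, 1].  This is the form that reproduces, to four decimals,
the published external-test intervals this package's acceptance suite
checks against; an exact Clopper–Pearson mode (on the rescaled
proportion (mcc+1)/2 with n trials) is available via
`method="clopper-pearson"` and is the required route for negative MCCs.
That n is the evaluation-set size is inferred from numeric agreement
with the published intervals rather than stated anywhere; the same
construction is applied when the machinery is pointed at recall.

Model comparison recovers each SE from the interval width
(`width/3.92`), combines them in quadrature, and evaluates the exact
two-sided normal tail probability of `Z = ΔMCC/ΔSE` (no Z-table).  The
p-value is two-sided — the published "not significant" annotation at
|Z| ≈ 1.81 only holds two-sided.  Reports render p below 1e-5 as
"<0.00001".  No multiple-testing correction is applied, matching the
procedure being reproduced.

## Re-initialization strategies

* **cold-R**: He-initialized random weights.
* **cold-I**: the source-task-pretrained backbone with a **fresh,
  zero-initialized 2-unit head** — the analogue of putting a new task
  head on a natural-image-pretrained backbone.  (Copying the source
  head as well produced negative transfer in calibration: the head is
  tuned to the source classes and starts the run far from the target
  prior.)
* **warm**: the previous checkpoint verbatim.
* **shrink**: `W' = αW + noise` applied to every trainable tensor,
  biases and head included (the checkpoint being shrunk was trained on
  the same task, so the head shapes match and there is no reason to
  exempt them).

β defaults to 0.01.  `noise_mode="gaussian"` (default) draws i.i.d.
zero-mean noise with standard deviation β, following the original
shrink-and-perturb recipe; `noise_mode="constant"` adds the literal
scalar β, preserving the plain-equation reading.  Both are seeded.

The α search is Bayesian optimization with a Gaussian process
(Matern-5/2 kernel, expected-improvement acquisition over random
candidates) on the interval [0.1, 0.9]; the reference budget is 100
objective calls with 30 random starts, and the returned α is the argmin
over every evaluated point.  Each objective call trains a
shrink-initialized model with a fixed per-call seed (whether the
full-scale procedure reused one seed per trial is unstated; fixing it
makes the search objective deterministic).

The training driver uses Adam and softmax cross-entropy and returns the
weights at the epoch of **minimum validation loss** (epoch 0, the
untrained initialization, included), never the final epoch.

## Weight-level ensembles

Mergeable models must share an architecture fingerprint (ordered layer
names and shapes).  EWA is the per-layer mean.  F-SLSQP minimizes
`1 − F_validation(merged)` over the coefficient simplex with SLSQP under
the equality constraint and [0,1] bounds.  Two practical points:

* The F-score of each candidate is computed at that candidate's **own**
  re-selected max-F threshold, consistent with the global thresholding
  rule (a fixed 0.5 threshold is the documented alternative).
* The objective is piecewise constant (an F-score over a finite
  validation set), so SLSQP's numerical gradient vanishes almost
  everywhere and most restarts terminate at their start point.  The
  implementation therefore tracks the global best across *all*
  objective evaluations, draws restart starts uniformly from the
  simplex (Dirichlet(1,…,1), seeded), and seeds the first restart at
  the equal-weights point — guaranteeing the result is never worse than
  EWA.  Evaluations are cached on the coefficient vector rounded to 6
  decimals.

Any non-trainable statistics a backbone carried would be merged with the
same coefficients; the backbones here have none.  Prediction-level
(probability-averaging) ensembles are deliberately out of scope.

The weight-similarity diagnostic is the 1-D Wasserstein-1 distance
between the empirical distributions of all flattened parameters of two
models, exported as a labeled square CSV.

## AGELFS

Frozen constituents → per-model GAP feature vectors → concatenation
(width D = Σ feature widths) → attention gate → dense 2-unit head →
learnable fuzzy softmax.  The attention variant is a learned gating
vector: a D×D dense projection of the concatenated features passed
through a conventional softmax, applied multiplicatively feature-wise.
This is the simplest mechanism that derives attention-based weights for
the concatenated outputs; the variant tag leaves room for dot-product
attention.  Only the gate, the head and the fuzziness are trainable —
constituent parameter hashes are asserted unchanged after training.

The LFS input is the dense head's raw scores by default
(`lfs_input="logits"`, the normative reading of the formula); the
literal softmax-then-LFS composition is available via
`lfs_input="probabilities"`.  Fuzziness is kept positive by a softplus
reparameterization initialized at exactly 1.0, where the LFS is the
conventional softmax; learned values on the mini-study land near 1.2.
Since the constituents are frozen, their features are computed once and
the head is trained on the cached feature matrix.

## Synthetic data

Images are 64×64 (default; a stand-in for 256×256 — the pipeline's
semantics, not resolution, is what is preserved), normalized to [0,1]
and representing already-cropped fields of view (lung segmentation is
out of scope).  A normal image is a patient-specific brightness offset
(σ = 0.05) plus a large-scale smooth background field (Gaussian-filtered
noise at scale size/4, amplitude 0.08) plus pixel noise (σ = 0.03).  An
abnormal image adds 2–4 Gaussian-blob opacities of width 0.06–0.10·size
and amplitude `0.45·class_separation·U(0.8,1.2)`.  The background
varies at a much larger spatial scale than the lesions, so the classes
are separable by shape rather than global brightness.  With
`class_separation=0` the abnormal class is statistically identical to
normal and trained models score chance MCC (a tested null).

Splits are patient-level 70/10/20; the P stage is the first ⌈n/2⌉
images of the F-stage train and validation sets (a patient whose images
straddle the boundary still lives only in "train"); the internal test is
shared by both stages.  Class imbalance defaults to 0.67 abnormal at the
patient level (≈2:1).

External test sets are covariate-shifted copies of the internal test:
blur (degrading lesion morphology), contrast compression, brightness
offset, and — essentially — fresh acquisition noise added *after* the
blur.  Without re-noising, blurring denoises the images and a mild
"shift" can help a fixed model.  Four presets of increasing severity
stand in for an external adult cohort and three pediatric strata; the
severity ordering is chosen so a fixed model's MCC degrades with
severity.

Source-task pretraining (the stand-in for natural-image pretraining)
trains the backbone on an auxiliary problem — oriented gratings vs soft
bright bumps on the same background process — for 8 epochs on 256
generated images.  The task is distinct from the target, but solving it
requires blob- and edge-sensitive filters at lesion-like scales, which
is exactly the feature reuse full-scale pretraining provides.

The standard fixture ("cxr-mini") is 300 patients, one image each,
64×64, separation 1.0, seed-deterministic.

## Desk-scale training defaults

Backbone: three conv blocks (8/16/32 channels, 3×3 kernels, ReLU, 2×2
max-pool) ending at the deepest pooling layer, then GAP and a dense
2-unit softmax head (~6.5k parameters), in float64 numpy.  Mini-study
training uses Adam at lr 3e-3, batch 32, 14 epochs per model (the
full-scale reference values — lr 1e-3, batch 64 — remain the config
defaults of `TrainingRunSpec`; the mini-study overrides them because a
6.5k-parameter model on 210 images needs a hotter optimizer to converge
within a desk-scale budget).  The mini-study α search uses 6 calls / 3
random starts with 3-epoch trainings, then retrains the winner at full
epochs; F-SLSQP uses 10 restarts; AGELFS trains 15 epochs on cached
features.  The full grid (8 models + 3 ensembles + 5 test sets) runs in
about 2.5 minutes on one CPU.

## What the synthetic experiments do and do not show

They exercise every pipeline contract end to end — split hygiene,
checkpointing, seeded reproducibility, threshold selection, ensemble
algebra, CI/Z-test reporting — and reproduce the full-scale study's
qualitative signatures: pretrained initialization reaches the cold
model's best validation loss in no more epochs, external shifts degrade
every reported model relative to internal testing, and the learned
fuzziness stays near 1.  They do **not** establish anything about real
radiographs: the lesion model is a Gaussian blob, not pathology; there
is no acquisition physics, no DICOM metadata, no reader noise; and the
60-image internal test makes single-model MCCs coarse (several saturate
at 1.0).  Absolute metric values are therefore not comparable with the
full-scale study — only the statistical machinery is, and that is what
the acceptance suite pins exactly.

## Numerical notes and edge cases

* Softmax and the LFS are stabilized by max-subtraction; at extreme
  `fuzziness · spread` products the off-mode probabilities underflow to
  exactly 0.
* The proportion-style CI errors on negative MCC and points the caller
  to the Clopper–Pearson mode; the experiment driver switches
  automatically when a model scores below 0.
* `ΔSE = 0` with `ΔMCC ≠ 0` is an error (Z undefined); with
  `ΔMCC = 0` it returns Z = 0, p = 1.
* Max-pooling ties propagate gradient to every argmax location.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical spec + seed reproduces
  weights bit-for-bit.

## Known limitations

* The attention gate is one of many reasonable attention forms; the
  reference description names no equation, so the gate is a documented
  assumption (as is the head's plain bias, no regularization).
* The GP optimizer is a compact EI implementation, not a drop-in clone
  of any particular library's `gp_minimize`; its budget semantics
  (n_calls, random starts, bounds, argmin-over-history) match the
  reference procedure.
* The mini-study's P-stage models are weak enough that a mild external
  shift can occasionally score above their internal MCC on a 60-image
  test; the external-generalization property is asserted for the
  full-stage models that the external comparison tables actually report.
* Checkpoints are stored as `.npz` plus a JSON layer manifest — portable
  across runs of this package, not across frameworks.
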