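# Methods

## Problem

A coronary-artery segment imaged by CCTA is reconstructed as two roughly
orthogonal curved multiplanar (MPR) views and carries a single weak binary
label: *culprit* (contains the lesion responsible for the infarction) or
*non-culprit*.  Only a small sub-region of either view determines the label,
the culprit class is rare (~12 %), and segments are grouped under patients.
`mvfuse` implements a learned two-view fusion classifier for this setting,
its comparator architectures, the training recipe for class imbalance, and
the patient-wise repeated cross-validation protocol — all exercisable on a
synthetic phantom cohort.

## Model

Let x⁽¹⁾, x⁽²⁾ be the two views.  A single residual CNN backbone f (applied
to both views — Siamese weight sharing) maps each view to a spatial grid of
L feature vectors qᵢ ∈ ℝᴰ.  A shared linear map P ∈ ℝ^{M×D} (M < D) projects
every vector, and the 2L projected vectors are stacked into the instance
matrix Q̃ ∈ ℝ^{2L×M}.  Content attention scores every instance

    sₖ = wᵀ tanh(V q̃ₖ)        (optionally gated: wᵀ[tanh(V q̃ₖ) ⊙ σ(U q̃ₖ)])

and the segment representation is the convex combination

    a = softmax(s),   z = Σₖ aₖ q̃ₖ,

classified by a fully-connected head ending in one sigmoid logit,
ŷ = σ(hᵀz + b) ∈ [0, 1].  This is multiple-instance learning with attention
pooling: the bag is the segment, the instances are spatial feature vectors
from *both* views, and `a` is an interpretable per-region importance map.

Implementation detail: the forward pass evaluates the softmax via per-view
partial sums joined only by commutative operations (elementwise max for the
stability shift, addition for numerator/denominator), so the score is
*bit-identical* under a view swap — the symmetry the Siamese design implies,
held exactly rather than to float tolerance.

### Backbone ("depth-14" residual plan)

Default: stem 3×3 conv (stride 2) + four stages of basic blocks
(conv-norm-relu-conv-norm, additive shortcut), widths (16, 32, 64, 128),
blocks (1, 2, 2, 1), stage strides (1, 2, 2, 2).  That is 13 convolutions
plus the classifier — 14 weighted layers, total stride 16, so a 96 px input
yields a 6×6 grid (L = 36).  Normalisation is a per-sample layer norm over
(C, H, W) with a channel affine: batch-independent, hence deterministic at
evaluation and compatible with the exact swap symmetry.  Backbone
activations are slightly leaky (slope 0.05) so no unit can die permanently,
and optional dropout on the projected instance vectors (training only,
seeded, off at evaluation) counters per-example memorisation — at desk scale
the network can otherwise fit every training image's noise fingerprint.
Two reduced presets — `small` (3 stages, widths 16/32/48) and `tiny`
(8/16/32) — let the whole pipeline train on one CPU core.

The numeric core is a small reverse-mode autodiff engine on numpy
(`mvfuse.autodiff`): broadcasting arithmetic, matmul, im2col convolution,
softmax, axis reductions, and Adam with optional decoupled weight decay.

### Comparators

* **Views as channels** — the two views stacked as a 2-channel input to one
  backbone; same projection/attention/head over the single L-instance grid.
  Not symmetric under view swap (channel order matters), by construction.
* **Feature concatenation** — per-view backbone grids globally max-pooled to
  two D-vectors, concatenated, classified by the fully-connected head.
* **Naive** — a coin flip at the training prevalence; its expected panel has
  the closed form sens = PPV = F1 = p, spec = 1 − p, acc = p² + (1 − p)².

## Training

Binary focal loss with p_t = ŷ for positives, 1 − ŷ for negatives:

    loss = −α_t (1 − p_t)^γ log(p_t),     γ ≥ 0, scores clamped at 1e-7.

γ = 0 (with α none) recovers cross-entropy exactly; default γ = 2, α none.
Balanced batch sampling: every mini-batch holds exactly batch_size/2
positives and negatives; the majority class is dealt without replacement
(epoch length ⌈n_maj/(b/2)⌉; the final batch tops up its majority slots from
earlier batches, so duplicates are confined to < b/2 per epoch and vanish
when the majority count divides evenly), the minority class is over-sampled
with replacement.  Optimizer Adam, lr 1e-3, default 30 epochs, no schedule,
no augmentation.  The full loop is a pure function of
(init_seed, shuffle_seed, dataset).

## Evaluation protocol

Patients are stratified by "has ≥ 1 culprit segment" and dealt greedily
(shuffled within stratum, to the currently smallest fold), giving fold sizes
and per-stratum counts within ±1 — this also covers strata smaller than k,
where standard stratified k-fold splitters refuse.  The complete k-fold CV
(k = 5) is repeated (default 5×); folds stay fixed across repeats and only
the sample order seen by the optimiser changes (`refold` re-draws folds).
Per fold×repeat evaluation: the operating threshold maximises F1 on that
evaluation's own validation scores (candidates are midpoints of consecutive
sorted unique scores plus ±∞ sentinels, ties toward the higher threshold);
the panel F1 / PPV / sensitivity / specificity / accuracy / AUC is
aggregated as mean ± sample SD (ddof = 1) over all fold×repeat evaluations
(not over repeat-level means).  AUC is the Mann–Whitney statistic (ties
half-counted), computed via scikit-learn; ROC staircases are emitted as CSV
and their trapezoidal area equals the AUC to 1e-9.  Empty-denominator
conventions: PPV = 0 with no positive predictions, sensitivity = 0 with no
positives, F1 = 0 when both are 0.

## Synthetic phantom world

Each view is a bright tube (nominal intensity 0.85) of roughly constant
radius (4.5–7.5 % of the image side) along a random quadratic Bézier
spanning the image, over a darker background (nominal 0.2) with i.i.d.
Gaussian pixel noise (SD 0.05), quantised to 8-bit PNG.  Vessel and
background levels are jittered per view (±0.08 / ±0.04) so that absolute
brightness is a nuisance variable: without this the phantom admits a global
brightness shortcut that competes with the localized-lesion feature the
generator exists to pose.  The two views of a segment have
independent geometries (including a random horizontal/vertical orientation),
emulating orthogonal reconstruction planes.  A culprit lesion is a smooth
cosine-bump narrowing of the tube radius (fractional depth `severity`; 1.0
interrupts the tube) plus an intensity drop toward `contrast` × the vessel
level, over ~22 % of the arclength; its longitudinal position is shared
between the views, while per-view visibility (both / one / mixed) is
controlled explicitly.  Cohort structure mirrors the clinical dataset the
package targets: 80 patients × ~6.425 segments (≈514 total), i.i.d.
Bernoulli(0.123) culprit labels.

What the phantom does *not* model: plaque morphology and texture, calcium,
branching vessels, spatially correlated CT noise, view-angle adjustment
error, per-patient correlation of culprit status.  A green end-to-end test
therefore establishes that the implementation can learn a localized
along-vessel deviation from weak labels and fuse asymmetric two-view
evidence — not clinical performance.

## Reduced test protocol and observed behaviour

The end-to-end learning checks run at desk scale: 48 px views, the `small`
backbone with dropout 0.5, 10 epochs, k = 5 with 2 repeats (and, for the
fusion-vs-channels comparison on single-view lesions, the `tiny` backbone
with one stratified 4:1 patient split per seed over 3 fixed seeds).  The
high-visibility lesion regime used there (severity 1.0, contrast 0.1) makes
the culprit signal unambiguous to a radiologist's eye; residual errors are
attributable to the learner, not the world.  At this scale run-to-run
variation by initialisation seed remains substantial (fresh-cohort AUC
mostly 0.95–1.0 with occasional runs near 0.6–0.8 that latch onto weaker
features); small validation folds (~100 segments, ~12 positives) add further
AUC noise of ±0.07 or so per evaluation.  The protocol's mean over
fold×repeat evaluations absorbs most of this variance.

## Numerical choices

* float32 throughout the network; metrics in float64.
* Scores clamped to [1e-7, 1 − 1e-7] inside the loss only.
* Attention normalisation asserted to 1e-6 (float32 softmax round-off).
* He fan-in initialisation for convolutions and hidden layers; unit-scale
  fan-in for projection, attention and output layers; all seeded.
* Max-pool gradients route to the first arg-max on ties.
* Greedy fold dealing breaks size ties toward the lower fold index.

## Known limitations

* No GPU path and no mini-batch parallelism; wall-clock scales linearly
  with epochs × segments (≈3 s/epoch for 514 48-px segments on one core).
* No early stopping or model selection inside a fold; the epoch budget is a
  fixed hyperparameter.
* The F1-maximising threshold is selected on the same validation scores it
  is evaluated on (the protocol's convention), which is optimistic for the
  thresholded metrics; AUC is unaffected.
* The autodiff engine supports exactly the operations the models need; it
  is not a general-purpose framework.
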