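# Methods

This note records the scientific and numerical choices behind
`mpcstanet`: what each stage computes, the parameters that matter, what
the synthetic fixtures do and do not establish, and where the design was
genuinely open.

## Problem setting

The package targets four-way staging of Alzheimer's disease from 2-D
brain MRI slices: Non-Demented (ND), Very Mild (VMD), Mild (MD) and
Moderate Demented (MOD).  Two properties of real staging collections
drive the design: a severe class skew (roughly 50/35/14/1 % across the
four stages) and disease signal that is subtle and spatially scattered
(ventricle enlargement, sulcal widening, hippocampal atrophy).  The
pipeline answers the first with class-balancing preprocessing and the
second with three architectural modifications of a ResNet50 backbone.

## Synthetic phantom fixtures

`synthetic_fixtures` fabricates datasets with the organisation and
statistics of a real staging collection — one directory per class, a CSV
manifest, grayscale images in [0, 255], counts following the 3200/2240/
896/64 skew or its 1/16 desk scaling 200/140/56/4 — from parametric
phantoms rather than patient data.

Each phantom is a bright ellipse (intensity ≈ 170) with a brighter
cortical rim (≈ 200) on a dark background (≈ 15), cut by eight dark
radial "sulcal gaps" and two central dark "ventricles" (≈ 25), plus
additive Gaussian texture noise (default σ = 6 intensity units).  The
class signal is carried by the ventricle semi-axis fraction, strictly
increasing 0.10 / 0.17 / 0.25 / 0.35 across ND → VMD → MD → MOD, with
the sulcal gap width growing alongside.  Mild geometric jitter (centre
±2 % of the image, axes ±4 %, spoke rotation) gives intra-class
variability.  All randomness derives from
`SeedSequence([seed, class_index, image_index])` with separate
substreams for geometry and noise, so images are bit-reproducible and
the zero-noise image equals its geometric template exactly.

What the phantoms are *not*: anatomically realistic, volumetric, or
representative of MRI contrast, acquisition artefacts, or inter-patient
variability.  A model that separates phantoms has demonstrated that the
pipeline — balancing, batching, optimisation, evaluation — is sound; it
has demonstrated nothing about accuracy on patient data, and the test
suite never claims otherwise.

## Class balancing

`plan_balance` lifts every class to the majority count.  The deficit is
filled first by data expansion — at most three augmented variants per
original, produced by cycling complete passes of (flip, Gaussian noise,
contrast adjustment) over the class's originals in manifest order — and
any remainder by SMOTE.  The augmentation/SMOTE proportions are a design
choice of this package; the method prescribes both operations but not
their split.  On the reference skew this yields: VMD 960 augmented, MD
2304 augmented, MOD 192 augmented + 2944 SMOTE, every class ending at
3200 (total 12,800; a 7:2:1 split then gives 8,960/2,560/1,280).

Augmentation defaults (the method names the operations but no values):
horizontal flip; noise σ = 10 intensity units, clipped and rounded back
to [0, 255]; contrast factors cycling 0.8/1.2 about each image's own
mean.  `adjust_contrast(…, 0)` is defined (a flat image at the rounded
mean, the formula's limit); negative factors are rejected.

SMOTE operates per class on flattened raw pixel vectors (16,384-d at
128²) of the originals + augmented pool — raw pixels are the only
representation constructed before the network, and drawing neighbours
from the augmented pool as well is a package decision.  For each base
sample `a`, its K = 5 Euclidean nearest neighbours are found once (K
follows the original SMOTE publication; it is not prescribed here), and
each of N syntheses picks a uniform neighbour `b` and a fresh
u ~ U(0, 1):

    x_new = a + u · |a − b|        (componentwise)

This absolute-difference form is deliberately kept as the default even
though it differs from canonical SMOTE, `a + u·(b − a)`: it is what the
method prescribes, and it can overshoot both endpoints (a = 5, b = 1,
u = 0.5 gives 7).  The canonical form is available behind
`canonical=True` / `--smote-canonical`.  N is derived per class as
⌈n_smote / T⌉ with excess synthetics truncated deterministically from
the end.  The default SMOTE seed is 42; neighbour choice and u draw from
independent substreams.

The 7:2:1 split is stratified per class: floor allocation by ratio, the
remainder going to the largest fractional parts, ties broken in
partition order (train, test, validation).  Classes smaller than three
records trigger a warning and best-effort allocation.

## Architecture

`assemble_variant` builds the ResNet50 topology (stem; stages of 3/4/6/3
blocks with bottleneck widths 64/128/256/512; global average pool;
fully connected head) with three independent switches.

**Dilated stem (DC).**  The 7×7 stride-2 stem convolution gets dilation
r = 2 and padding 6 instead of r = 1, p = 3.  Effective kernel
K = k + (k−1)(r−1) (so 13 for k = 7, and 5 in the worked 3×3 example);
output size W₂ = ⌊(W₁ + 2p − r(k−1) − 1)/s⌋ + 1.  p = 6 is the unique
padding preserving both the output size and the parameter count — the
published equality of the baseline and DC budgets forces it.  One
caveat, verified numerically: on a constant image the plain and dilated
stems agree only where every kernel tap lands inside the image; the
zero-padded border rows engage different weight subsets, so full-map
equality does not hold.

**Multi-Phantom Residual Block (MPRB).**  The linear branch is 1×1 conv
→ BN → ReLU, a four-way channel split (each group mid/4 wide) processed
by parallel branches — 1×1; 1×1 then 3×3 (pad 1); 1×1 then 5×5 (pad 2);
3×3 max-pool (stride 1, pad 1) then 1×1 — re-concatenated to mid
channels, BN → ReLU, optionally a residual attention step (below), then
1×1 conv → BN.  The downsampling (conv-kind) shortcut is 2×2 average
pool (stride 2) → 1×1 conv → BN; identity-kind shortcuts are pure
identities, per ResNet convention.  Where a stage's first block does not
downsample (the first stage), the conv-kind shortcut drops the pool,
since the pool's role is the spatial reduction; spatial stride sits on
the first 1×1 convolution, mirroring the backbone.  The four-way split
with thin branches is what compresses the network below the baseline
budget.

**Space Conversion Attention (SCAM).**  For input X (C×H×W): row
descriptors h_i ∈ ℝ^C (mean over width) attend over each other with
scores e_ij = h_i·h_j/√C, softmax-normalised over j, giving a vertical
context c_I (C×H); columns give c_II (C×W) symmetrically.  The score
function is *not* prescribed by the method; this parameter-free scaled
dot product is the package's instantiation, chosen so SCAM's only
learnable weight is the fusion projection and budgets stay auditable.
Contexts are broadcast to C×H×W; their sum, their elementwise max and
both contexts are concatenated (4C×H×W), projected by a biased 1×1
convolution F_h (no normalisation) and squashed: Weight = σ(F_h(SPA)),
applied as a multiplicative gate X ⊙ Weight.  Ties in the max route
gradient to the vertical context.  In stock bottlenecks (SCAM-only
variants) the gate is applied to the 3×3 convolution's output; inside
MPRB, the concat-stage output Y becomes Y + SCAM(Y) (residual
attention between the multi-branch convolution and the closing 1×1).

**Parameter accounting.**  `count_parameters` counts every trainable
array element exactly; "millions" rounds half-up to two decimals.
Budgets are reported with the canonical 1000-way head so they are
comparable with published ResNet50 figures (training uses a 4-way
head).  The baseline counts 25,557,032 → 25.56 M, and DC variants are
bit-identical in count.  Because e_ij and the branch widths are
underdetermined by the method, the MPRB/SCAM budgets are not expected to
match the originally reported 21.10/31.17/27.25 M exactly; this
implementation gives 17.23 M (MPRB), 30.59 M (SCAM) and 22.26 M (full),
preserving the reported strict ordering MPRB < baseline < SCAM with the
full model strictly between, which is what the tests assert.

## Training and evaluation

Mini-batch training with Adam (canonical β = (0.9, 0.999), ε = 1e-8 —
only the learning rate 1e-3 is prescribed), cross-entropy loss, batch
32 for training and 8 for evaluation.  The published schedule is 140
epochs; desk-scale runs default to 5.  Epoch shuffles are seeded;
non-finite loss aborts with a diagnostic.  Weight initialisation is
Kaiming-normal (fan-out) for convolutions, unit/zero for BN, uniform
±1/√fan_in for the head, all from a per-model seeded generator.
Grayscale inputs are scaled to [−1, 1] and replicated to three channels
so the canonical stem and its budget apply.

Metrics come from argmax predictions: a 4×4 confusion matrix (rows =
truth, order ND, VMD, MD, MOD), per-class precision/recall/F1 (0 with a
logged warning where undefined), accuracy = trace/total, and macro mAP —
the macro mean over classes present in the truth of one-vs-rest average
precision on softmax scores (all-points interpolation, via
scikit-learn).  The mAP definition is this package's, documented so
cross-network comparisons are interpretable.

## Numerical engine

No deep-learning framework is used: the network runs on a compact
reverse-mode autodiff engine (`_engine.py`) over float32 numpy arrays —
im2col convolution feeding BLAS matmuls, −∞-padded max-pooling, a fused
batch-norm primitive with the closed-form gradient (ε = 1e-5, momentum
0.1, biased batch variance, running stats excluded from parameter
counts), and Adam.  Every primitive's gradient is checked against
central finite differences in float64 in the test suite, and the
vectorized attention path is checked against an independent nested-loop
implementation to 1e-5.

## Problem sizes in the test suite

Training-dependent tests run at sizes chosen for a single-CPU desk
setting: the full-model separability check uses the 1/16-scale balanced
fixtures (800 images) rendered at 32×32 px — the generator's minimum
size, at which the ventricle signal is still several pixels wide — and
stops as soon as held-out accuracy exceeds 90 % (typically epoch 3).
Direction-of-effect and learnability tests use a depth-reduced variant
(one block per stage, width 8).  Exact-count checks (budgets, balancing,
split) run at full architectural size or full reference counts, since
they involve no training.

## Known limitations

- Phantom separability is by construction; no claim transfers to MRI
  data, and the published real-data accuracies (≈ 96 % overall) are out
  of scope without the external collection and full-length training.
- The literal SMOTE form can leave the convex hull of the class and, on
  pixel data, saturate against the intensity ceiling; the canonical
  switch exists for users who want textbook behaviour.
- MPRB/SCAM budgets match the reported ordering, not the reported
  magnitudes (score function and branch widths underdetermined, above).
- The engine is CPU-only and single-threaded beyond BLAS; it is built
  for correctness and desk-scale experiments, not production training
  throughput.
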