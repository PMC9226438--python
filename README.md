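# mpcstanet

Staging Alzheimer's disease from 2-D brain MRI slices, for researchers
studying class-imbalanced medical image classification: a class-balancing
preprocessor (data expansion + SMOTE) feeding **MPC-STANet**, a ResNet50
backbone modified with a dilated stem, Multi-Phantom Residual Blocks and
a two-axis Space Conversion Attention gate.  The whole pipeline runs on
synthetic phantom fixtures, so every stage is testable on a desk without
any patient data, downloads, or GPU — the network runs on a compact
numpy autodiff engine included in the package.

## The method

**Classes.**  Four stages: Non-Demented (ND), Very Mild (VMD), Mild
(MD) and Moderate Demented (MOD), with a reference skew of
3200/2240/896/64 images (50/35/14/1 %).

**Class balancing.**  Every class is lifted to the majority count:
first by cycling (flip, Gaussian noise σ=10, contrast 0.8/1.2) over the
class's originals (at most three augmented variants each), then by
SMOTE on flattened pixel vectors.  A base sample *a* picks one of its
K = 5 Euclidean nearest neighbours *b* and u ~ U(0,1):

    x_new = a + u · |a − b|   (componentwise; seed 42)

The absolute-difference form is the method's own (it can overshoot both
endpoints); the textbook `a + u·(b − a)` sits behind a
`--smote-canonical` switch.  A stratified 7:2:1 split follows.

**Architecture.**  Three independent switches on ResNet50:

- *DC* — the 7×7 stem convolution becomes dilated (r = 2, p = 6):
  effective kernel K = k + (k−1)(r−1), output size
  W₂ = ⌊(W₁ + 2p − r(k−1) − 1)/s⌋ + 1, at identical parameter count.
- *MPRB* — each bottleneck becomes a Multi-Phantom Residual Block: a
  four-way channel split into parallel 1×1 / 3×3 / 5×5 / pooled-1×1
  branches, re-concatenated, with an average-pool projection shortcut
  on downsampling blocks.
- *SCAM* — row and column context vectors from axis-wise attention
  (scores hᵢ·hⱼ/√C), fused by sum, elementwise max and concatenation,
  projected by a 1×1 convolution and applied as a logistic gate
  X ⊙ σ(F_h(SPA)).

See `docs/methods.md` for every formula, default and design decision.

## Worked example

Balance a 1/16-scale phantom replica of the reference skew and inspect
the plan:

```python
import mpcstanet as m

spec = m.PhantomSpec(image_size=128, seed=0)
dataset = m.generate_dataset(
    m.ClassDistribution(dict(m.DESK_SCALE_COUNTS)), spec)
print("original:", dataset.distribution().counts)

plan = m.plan_balance(dataset.distribution())
for label in m.CLASS_LABELS:
    q = plan.quotas[label]
    print(f"{label:>4}: keep {q.n_keep_original:3d}  "
          f"augment {q.n_augmented:3d}  smote {q.n_smote:3d}")

balanced = m.balance_dataset(dataset, plan,
                             m.SmoteParams(seed=42),
                             m.AugmentationConfig(seed=0))
print("balanced:", balanced.distribution().counts)

split = m.split_dataset(balanced, m.SplitSpec(seed=0))
print("split:", len(split.train), len(split.test), len(split.validation))

budget = m.count_parameters(m.assemble_variant(m.VariantSpec(True, True, True)))
print("MPC-STANet budget:", budget)
```

prints

```
original: {'ND': 200, 'VMD': 140, 'MD': 56, 'MOD': 4}
  ND: keep 200  augment   0  smote   0
 VMD: keep 140  augment  60  smote   0
  MD: keep  56  augment 144  smote   0
 MOD: keep   4  augment  12  smote 184
balanced: {'ND': 200, 'VMD': 200, 'MD': 200, 'MOD': 200}
split: 560 160 80
MPC-STANet budget: 22.26M (22,259,944)
```

Each minority class ends at the majority count of 200: VMD and MD need
only augmentation (deficits of 60 and 144 fit within three variants per
original), while MOD's four originals yield 12 augmented images and the
remaining 184 come from SMOTE.  The 7:2:1 split of the 800 balanced
images gives 560/160/80.  The budget line is the exact trainable
parameter count of the full model with the 1000-way budget head.

The ablation grid (`mpcsta ablate`) prints every variant's exact count
beside the originally published budgets and accuracies:

```
Variant                       Params  Millions  Published M  Published acc %
----------------------------------------------------------------------------
ResNet50                  25,557,032     25.56        25.56             84.6
ResNet50-DC               25,557,032     25.56        25.56             86.7
ResNet50-MPRB             17,226,280     17.23        21.10             89.5
ResNet50-SCAM             30,590,696     30.59        31.17             90.1
ResNet50-DC-MPRB          17,226,280     17.23        21.10             93.3
ResNet50-DC-SCAM          30,590,696     30.59        31.17             93.8
ResNet50-MPRB-SCAM        22,259,944     22.26        27.25             94.6
MPC-STANet                22,259,944     22.26        27.25             96.2
```

The baseline and DC rows reproduce the published 25.56 M exactly;
dilation never changes a count.  The MPRB/SCAM rows preserve the
published *ordering* (MPRB compresses, SCAM grows, the full model lies
between) but not the exact magnitudes — the attention score function
and branch widths are underdetermined, see `docs/methods.md`.

Other entry points: `mpcsta fixtures | balance | split | train |
evaluate | count-params | run` (`mpcsta run --out DIR` executes the
whole pipeline end-to-end from one YAML config).

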