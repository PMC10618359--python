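# Methods

## Problem and pipeline

Dried shiitake mushrooms are sorted into six commercial grades that differ in
cap texture (the prized "flower" cracking pattern), thickness and color.
Photographs show a single dark mushroom on a near-white white-balance card, so
grading decomposes into: locate the mushroom (global threshold → contours →
square crop), standardize (bicubic resize to 224×224, augmentation, 70/30
split), and classify (D-VGG, a compact residual VGG with channel attention).
Each stage is an independent module with its own contract; this note records
the models, the defaults and the judgment calls.

## Thresholding

Otsu's criterion selects the gray level t maximizing the between-class
variance σ_b²(t) = ω₀ω₁(μ₀−μ₁)² of the 256-bin histogram, with class 0 the
levels ≤ t. Exhaustive search evaluates all 256 levels; ties break toward the
smallest maximizer so results are reproducible. A one-level histogram is
returned with a `degenerate` flag rather than an error.

OOA-Otsu replaces the traversal with the osprey optimization algorithm, a
two-phase population metaheuristic on the continuous interval [0, 255]:

* **Phase 1 (exploration)** — member Xi moves toward a random "fish" SFi
  drawn from the set of strictly better members plus the incumbent best:
  candidate = Xi + r·(SFi − I·Xi), r ~ U(0,1), I ∈ {1, 2}.
* **Phase 2 (exploitation)** — a perturbation shrinking with the iteration
  counter t: candidate = Xi + (lb + r·(ub − lb))/t.

Candidates are clamped to the bounds and accepted greedily, so the incumbent
never worsens. Fitness is the *negated* variance of the rounded integer
level, memoized per level, so the count of distinct objective evaluations —
the quantity the speedup is about — is bounded by min(256, N(2T+1)).

Defaults N = 8, T = 8 give at most 136 distinct evaluations. On a 1-D
objective whose optimum sits on a broad plateau between two histogram modes,
this budget finds the exact exhaustive optimum essentially always (the test
suite requires ≥ 95% of 200 seeded images; observed 100%). The population
size and iteration count of the original study are not published; these
defaults were chosen once as the smallest round budget that preserves
near-certain optimality while staying well under 256 evaluations.

Masks default to dark-foreground polarity (pixel < t → 1), matching a dark
object on a light card; the opposite polarity is a named option.

## Segmentation

Grayscale uses ITU-R BT.601 luma (0.299/0.587/0.114), the dominant toolkit
convention. Foreground components are 8-connected; only external boundaries
are kept, because crack texture produces bright (hole) contours inside the
cap that are irrelevant to localization. The largest-area contour wins;
smaller residue speckles are discarded. Its bounding rectangle is expanded to
the minimum outer square (side = max(w, h), centered, corner floored), which
guarantees later resizing cannot distort the aspect ratio. If the square
crosses an image edge it is shifted inward; only if the side exceeds the
smaller image dimension is it reduced (and flagged). No margin is added by
default; `margin` is exposed for callers who want looser crops. Coordinates
are 0-based with half-open boxes, so cropping is pure slice arithmetic.

## Dataset protocol

Crops are resized to 224×224 with bicubic interpolation (Pillow). Each
original yields exactly five records: itself, horizontal flip, vertical flip,
a Gaussian-noise copy, and an equal-scale center zoom. The noise and zoom
parameters are not published; the defaults are σ = 12.75 gray levels (5% of
the range) and zoom 1.2, both config-exposed. Per-image noise streams derive
from the config seed plus the record index, so manifests are
order-independent.

Splitting acts on the *augmented* pool, per class, with a seeded shuffle and
round-half-up(0.7·n) training records — the only rounding rule that
reproduces every published per-grade train/test count (e.g. 1,115 → 781 and
1,325 → 928; totals 4,744/2,031). The fraction is converted through
`decimal.Decimal(str(f))` because binary floats land 0.7·1115 a hair below
780.5. Because augmentation precedes splitting, flips of a training image can
legitimately land in the test split; that leakage is in the protocol as
published, and callers can instead split first and augment the training
records only.

Model inputs are standardized per channel to mean 0.5 / sd 0.5 on the [0,1]
scale, i.e. x → (x/255 − 0.5)/0.5 ∈ [−1, 1].

## D-VGG architecture

Five stack blocks of widths 32, 64, 128, 256, 512. A stack is two 3×3
stride-1 same-padding convolutions, each followed by batch normalization,
with a 1×1 batch-normalized shortcut added before the final ReLU (the
shortcut carries no activation of its own — the standard residual
convention; the source figure leaves this open). Convolutions followed by BN
have no bias; ablating BN restores the biases. Each block ends with channel
attention and a 2×2/2 max pool, so a 224×224 input reaches the head as
7×7×512. The head is global average pooling → linear(512 → 6) → softmax;
with the GAP head ablated, the map is flattened instead.

The attention module squeezes each channel to the midpoint of its global
average and global maximum, z_c = (mean + max)/2, then excites through
linear(C → C/r) → ReLU6 → linear(C/r → C) → sigmoid and rescales the
channels. ReLU6 bounds the hidden activations, which keeps the channel
weights from saturating unevenly. The reduction ratio r is not published; r
= 16 (the original squeeze-and-excitation default) is used and is confirmed
by the parameter-count cross-check below. Both excitation linears carry
biases — with bias-free linears the published totals cannot be reproduced.

Parameter accounting (trainable scalars; BN running statistics are buffers):
stacks 4,890,368 + attention 44,702 + head 3,078 = 4,938,148 ≈ 4.94×10⁶.
Removing residual shortcuts and BN (biases restored) gives 4,760,004 ≈
4.76×10⁶. Both match the published ablation table. That table prints the
same 4.94×10⁶ for the no-attention variant, which cannot be right — removing
the attention blocks must shed ~0.045×10⁶ parameters — so the full-model and
no-residual/no-BN rows are treated as authoritative and the third as a
typographical duplicate.

Weights initialize Kaiming-uniform (U(±√(6/fan_in))), BN γ=1, β=0, one seeded
generator per model.

## Numerical engine

No deep-learning framework is a dependency; the layers (im2col convolution,
batch normalization, ReLU/ReLU6/sigmoid, max pool, GAP, linear, the attention
block) implement both forward and backward passes in NumPy, verified against
central finite differences across every parameter tensor. Batch
normalization uses the biased (1/m) batch variance, ε = 1e-5, and EMA running
statistics (momentum 0.1) for eval mode; train mode requires batches of ≥ 2.
Max-pool and max-squeeze backward route gradients to a single argmax per
window (ties broken by first index).

**Precise-BN recalibration.** Over short runs the EMA statistics average
activations of *stale* weights and can lag the final network enough to ruin
eval-mode accuracy while batch-statistic accuracy is near perfect. After each
epoch the trainer therefore recomputes the running statistics under the
current weights by a chunked pass over (up to 512 of) the training images —
the "precise BN" procedure. This affects only eval-mode normalization, never
the gradients.

## Training and evaluation

Adam (β = 0.9/0.999), initial learning rate 2e-4, batch size 32, 50 epochs,
shuffled mini-batches, focal loss — the published regimen — are the
`TrainConfig` defaults. The focal focusing exponent is not published; γ = 2
(the value standard in the focal-loss literature) is the default and γ = 0
recovers cross-entropy exactly (asserted in tests). No weight decay, LR
schedule or gradient clipping, since none is described. After every epoch the
held-out split is scored and the best-accuracy snapshot retained; the
held-out split doubles as validation and test set, as in the source protocol,
which slightly flatters the reported accuracy.

Metrics are one-vs-rest per class: TP/TN/FP/FN with ACC, precision,
specificity, recall, F1. The averaged metrics use the support-weighted mean
avg = Σ k_i·N_i / Σ N_i; the cited supplementary formula is unavailable, and
its symbols (a per-class metric k_i against a per-class count N_i) imply
exactly this weighting — an unweighted macro mean is also computed. A class
that receives no positive prediction has undefined precision; it is reported
as 0 and flagged.

## Synthetic fixtures

The generator emulates what the acquisition rig produces, not how mushrooms
look: a near-white card (level 235) with truncated Gaussian noise (σ = 8,
clipped at ±3σ so stated intensity bounds are deterministic), a dark filled
ellipse (random axes 14–22 px, rotation, position) for the cap, bright radial
polyline cracks (level 170) whose count scales with `crack_density` and whose
length stays ≤ 0.85 of the short semi-axis so the dark region stays
8-connected, and optional dark speckles outside the object. Ground truth is
the exact pixel support of the drawn ellipse, so segmentation IoU is measured
against the true bounding square, not an approximation.

The default three classes separate by cap gray {55, 75, 95} *and* crack
density {0.7, 0.35, 0}, making them learnable from mean intensity alone —
deliberately easy, because the end-to-end test asks whether the training
machinery works, not whether the architecture is strong. Passing on these
fixtures shows the pipeline is wired correctly end to end; it says nothing
about accuracy on real mushrooms, whose grade differences are subtle texture
contrasts under varying illumination.

## Scaled-down problem sizes

The end-to-end run used by tests and the acceptance script is 3 classes × 60
images (64×64 canvas, model input 32×32), a three-block model of widths
(8, 16, 32) with attention ratio 4, Adam at 1e-3 for 10 epochs — a size
chosen so the whole suite completes in well under a minute on one CPU while
still exercising every layer type, the augmentation/split arithmetic at the
published 1,355-image scale (with 1×1 placeholder images), the full-size
224×224 forward pass, 200 thresholding images and 50 segmentation images.
The learning rate is higher than the full-scale default because the run is
two orders of magnitude shorter; it was fixed once alongside the other
scaled-down choices.

## Known limitations

* The binarization "complete contour" percentages and all wall-clock numbers
  from the original study need its private 1,355-image dataset and hardware;
  they are out of scope. What is reproduced instead: the architecture's
  parameter totals, the augmentation/split arithmetic, the head geometry, and
  the optimizer's optimality/budget behavior.
* The NumPy engine is single-threaded-ish (BLAS aside) and meant for
  correctness and small-scale runs, not for training the full 224×224 model
  to convergence.
* One mushroom per frame is assumed, as in the acquisition rig; multi-object
  scenes, shadows and illumination correction are out of scope.
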