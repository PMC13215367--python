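# Methods

`metseg` re-creates, at desk scale, the training and evaluation machinery of
a lesion-focused 3D segmentation pipeline for multiple brain metastases
(BMs) on contrast-enhanced T1 MRI: a hybrid CNN-encoder / vision-transformer
/ CNN-decoder network, a patch-level focal loss that prioritises small
lesions, a supervised contrastive pretraining stage that separates lesion
and non-lesion latent tokens, and a lesion-wise detection/segmentation
evaluation protocol.  No clinical volumes ship with the package; everything
is exercised on seeded synthetic phantoms.

## The model

The network maps a volume of shape `s^3` through `n_down` stride-2
double-convolution stages (conv → instance norm → leaky ReLU, slope 0.01 —
plain ReLU lets a large Nesterov step kill entire decoder channels, after
which the output collapses to a constant it cannot escape) to an 8×8×8
bottleneck grid, constraint `s / 2^n_down = 8`, so the bottleneck always
holds L = 512 feature tokens.  A ViT — learned per-token positional
embedding plus pre-norm transformer blocks (default 6, configurable down to
2 for fast tests) — applies self-attention over the tokens.  The decoder
mirrors the encoder with nearest-neighbour ×2 upsampling, skip
concatenations, and a final 1×1×1 convolution with a two-class softmax
(lesion / background).  The encoder block layout (plain double conv blocks,
channel doubling capped at 8× base width) is this package's own choice; only
the encoder–ViT–decoder topology, the 8³ token grid and the 6-layer ViT
depth are fixed by the method being reproduced.

The latent field `z ∈ R^{d×L}` exposed to contrastive pretraining is the ViT
output; token `l` corresponds to bottleneck cell `l` in C-order raster, the
same order used when the lesion mask is max-pooled onto the 8³ grid.

Because no GPU autodiff framework is assumed, the package carries a compact
reverse-mode autodiff core (`metseg.autodiff`) over numpy arrays with a
fused conv3d primitive.  The network runs in float32; losses accept float64
inputs so finite-difference gradient checks keep full precision.  Every
primitive's vector-Jacobian product is tested against central differences.

## Losses

Total fine-tuning loss: `L = L_Dice + (1−w)·L_CE + w·L_LRP`, default
`w = 0.4` (the weight reported as optimal in the source study's sweep).

* `L_Dice = 1 − (2Σpg + ε)/(Σp + Σg + ε)`, ε = 1e−5.  The printed form of
  the objective writes the Dice *coefficient*; the loss is one minus it
  (minimisation convention).
* `L_CE` is the voxel-wise **mean** of −log p(correct class) (the printed
  form does not fix the normalisation; mean keeps the scale independent of
  volume size).
* `L_LRP` partitions the volume into non-overlapping 8×8×8-voxel patches.
  Patch label `y_l = 1` iff the patch contains ≥ 1 lesion voxel.  Patch
  presence probability `q_l` is the **max** of the voxel foreground
  probabilities in the patch (aggregation is not fixed by the printed
  method; max encodes "presence" directly and routes gradient to the
  strongest voxel; noisy-OR `1−Π(1−p)` is available via
  `LossConfig(aggregation="noisy_or")`).  The per-patch term is the
  two-sided focal cross-entropy
  `−[y(1−q)^γ log q + (1−y) q^γ log(1−q)]`, γ = 0.5, averaged over patches.
  The printed objective carries only the positive term (`y_l` factor), which
  would zero out every background patch and contradict the stated purpose of
  down-weighting easy negatives; the two-sided standard focal form is
  therefore the default and the literal one-sided form is kept behind
  `LossConfig(one_sided=True)`.
* Probabilities are squashed to [1e−7, 1−1e−7] before logs by the affine
  map `p → p(1−2ε)+ε` rather than hard-clamped: clamping kills the gradient
  exactly where a float32 softmax has saturated to 0 or 1, which can trap
  fine-tuning in an all-background state it cannot leave; the affine squash
  keeps the gradient alive everywhere (and is exact at p = 0.5).

## Contrastive latent pretraining (CLP)

The binary lesion mask is max-pooled onto the 8³ bottleneck grid (a cell is
positive iff it contains any lesion voxel — mean/nearest subsampling would
erase sub-cell lesions entirely).  For each anchor token `i` with `m_i = 1`:

* attraction: `−log( exp(s_ij) / Σ_{j′ pos, j′≠i} exp(s_ij′) )` summed over
  positives `j ≠ i`;
* repulsion: `+log( exp(s_ik) / Σ_{k′ neg} exp(s_ik′) )` summed over
  negatives `k`.

The attraction denominator runs over positives only, matching the method's
pseudo-code literally; the standard supervised-contrastive denominator
(positives + negatives) is available via `CLPConfig(denominator="supcon")`.
Similarities are `s_ab = z̃_a·z̃_b / T` with T = 1 and tokens
unit-normalised by default: the raw `exp(z·z)` similarity overflows for
unnormalised features, so `normalize_tokens=False` clamps similarities to
±50.  Volumes whose lesions vanish on the 8³ grid contribute no CLP loss and
are skipped.  Anchors/negatives beyond `max_anchors`/`max_negatives` (64/128
per volume) are subsampled with a seeded generator; the uncapped loss equals
a literal triple-loop oracle to 1e−5 and is what the tests check.

Latent class separation is summarised by `separation_score`: after
normalising every token dimension by the mean/SD of the lesion-free tokens,
the distance between class centroids divided by the mean within-class SD
(isotropic clouds shifted by k SDs score ≈ k).  `tsne_embed` provides the
matching 2D visualisation export.

## Two-stage schedule

Stage 1 optimises the CLP loss over encoder + ViT with the decoder frozen;
stage 2 freezes encoder + ViT and fine-tunes the decoder with the composite
loss.  Freezing is structural (frozen groups receive no gradient and are
bitwise unchanged — a tested contract).  Both stages use SGD with Nesterov
momentum 0.99 and a polynomial schedule `lr(t) = lr0·(1 − t/T)^0.9` from
lr0 = 0.001 (the poly exponent is not fixed by the source; 0.9 is the
nnU-Net convention).  Gradients are clipped at global norm 10.  Because the
encoder is frozen in stage 2, encoder/ViT features of each cohort volume are
computed once and cached; only the decoder runs per iteration.

Full-scale reference values (4000 + 4000 epochs × 201 iterations) are kept
in the config docstrings; desk-scale defaults are 30 + 30 epochs of
whole-volume batches (size 2) over a small cohort.  The desk-scale stage-2
experiments in the test suite and acceptance script use a larger initial
rate (see "Problem sizes" below): with only a few hundred optimisation steps
instead of ~800 000, the full-scale rate of 0.001 leaves the decoder far
from convergence, so the scaled runs raise lr0 once to the smallest value at
which the composite loss visibly converges, and keep every other
hyperparameter at its stated value.

## Synthetic phantoms

Each "patient" is a homogeneous background volume (level 100) containing
non-overlapping, randomly oriented ellipsoidal lesions rendered by the
voxel-center-in-ellipsoid rule, with intensity `background × contrast`,
contrast ~ U[1.4, 2.0], optional smooth multiplicative bias field (±10%),
and additive Gaussian noise (SD 5, ≈5% of background).  The mask is
noise-free.  Lesion longest-axis diameters follow the three-stratum mixture
observed in multi-institutional BM cohorts — 25.73% small (<3 mm), 40.92%
medium ([3, 6] mm), 33.35% large (>6 mm) — uniform within stratum, floor
1 mm (so sub-voxel lesions cannot vanish silently at 1 mm spacing), cap
12 mm by default.  Per-patient lesion counts follow a truncated geometric
law on [1, 50] (p = 0.18, mean ≈ 5.6): only the qualitative shape
(decreasing, capped near 50) is documented for the real cohorts, so the law
itself is a package choice.  Ellipsoid aspect ratios are U[0.6, 1] relative
to the longest semi-axis.

What the phantoms do *not* emulate: MRI physics (no PSF, no Rician noise,
no skull or anatomy), lesion texture/heterogeneity, non-ellipsoidal shapes,
and inter-lesion clustering.  Passing tests therefore demonstrate the
correctness and directional behaviour of the losses, schedule and protocol
— not clinical-grade detection performance.

`perturb_prediction` builds evaluation fixtures with known structure: per
lesion keep / drop / erode-to-coverage-f (retaining `round(f·|B|)` voxels
nearest the centroid), plus spurious balls disjoint from the ground truth.

## Evaluation protocol

Per patient: the predicted mask is closed with a structuring element
spanning ±1 mm per axis (a 3³ cube at 1 mm isotropic — a Euclidean ball of
radius 1 voxel cannot bridge single-voxel gaps, which is the point of the
clean-up); ground truth is used as-is.  Components are 26-connected.  Each
(prediction, GT) pair is scored by coverage `CV = |A∩B|/|B|`; pairs with
CV ≥ 0.5 are matched one-to-one greedily by descending CV (ties broken by
component id; an exhaustive-assignment oracle in the tests confirms the
greedy choice is optimal on small fixtures).  Unmatched predictions are FPs,
uncovered GT lesions FNs.  Lesion size is the longest 3D diameter (max
pairwise voxel-center distance; convex-hull shortcut beyond 300 voxels;
single voxels measure 0 mm).  Strata: small [0, 3) mm, medium [3, 6] mm
(closed interval, so the boundaries belong to medium), large (6, ∞) mm.
Per-lesion Dice is computed only for matched pairs with GT ≥ 3 mm.  FPs are
stratified by the predicted component's own size (they have no GT size).
Undefined ratios (empty strata, patients without GT lesions or without
predictions) are reported as missing and excluded from aggregates, never
zero-filled.

## Problem sizes and numerical choices

* Test/acceptance cohorts use 32³ volumes at 1 mm (two downsamplings to the
  8³ bottleneck) with reduced widths (base 4 channels, ViT depth 2,
  d = 16); the same code scales to 64³+/6-layer configurations.
* Desk-scale runs: CLP pretraining 10–30 epochs at lr0 = 0.001; stage-2
  sweep-style runs ~20 epochs at lr0 = 0.02 (chosen once as the smallest
  rate at which the composite loss converges in that budget).
* On a small phantom cohort, contrastive pretraining has an optimal
  duration: around 10 epochs (~160 steps on 16 phantoms) latent separation
  peaks and the subsequent decoder fine-tune benefits clearly (higher
  sensitivity *and* fewer false positives than from a random encoder);
  continuing to 20+ epochs over-separates the tokens, the separation score
  falls back, and stage 2 can collapse to all-background predictions it
  cannot escape.  The end-to-end pipeline therefore uses a 10-epoch stage 1
  by default, while the directional separation check (which only compares
  against random initialisation) also holds at 30 epochs.
* Dice ε = 1e−5; probability clamp 1e−7; similarity clamp ±50 (unnormalised
  CLP only); gradient clip norm 10.
* Determinism: all randomness flows from explicit `numpy` generators;
  per-patient seeds are spawned from the cohort seed via `SeedSequence`, and
  repeated runs reproduce NIfTI mask files byte-identically.

## Known limitations

* The one-sided printed focal form and the positives-only attraction
  denominator are implemented literally as options, but the defaults follow
  the stated intent (two-sided focal) and the pseudo-code (literal
  denominator) respectively; with other conventions results will differ.
* Greedy CV matching is order-independent but not globally optimal in
  pathological many-to-many overlap configurations larger than those the
  oracle covers.
* Instance normalisation couples distant voxels, so a purely local probe
  shifts all latent tokens slightly; token/cell correspondence is sharp only
  relative to that baseline.
* Desk-scale training budgets demonstrate directions (loss decreases,
  separation increases, small-lesion sensitivity responds to `w`), not
  converged clinical performance.
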