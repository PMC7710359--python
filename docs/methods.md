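# Methods

This note documents the models and procedures the package implements, the
defaults it ships, the design choices that were genuinely open, and what
the synthetic-data tests do and do not demonstrate.

## Consensus ground-truth estimation (STAPLE)

Binary expert masks D_ij (rater j, pixel i) are fused by
expectation-maximization over the latent true segmentation T:

* E-step: W_i = g·∏_j p_j^{D_ij}(1−p_j)^{1−D_ij} /
  [ that + (1−g)·∏_j (1−q_j)^{D_ij} q_j^{1−D_ij} ]
* M-step: p_j = Σ_i W_i D_ij / Σ_i W_i,
  q_j = Σ_i (1−W_i)(1−D_ij) / Σ_i (1−W_i)

Iteration stops when mean |ΔW| < `tol` (default 1e-7) or after
`max_iter` = 100 iterations. Choices that the algorithm statement leaves
open, fixed here for reproducibility:

* **Prior.** `prior="auto"` sets a spatially uniform g equal to the mean
  foreground fraction over all raters' masks. EM runs on the full pixel
  grid — not a trimmed bounding box — so g reflects the scene's true
  class imbalance.
* **Initialization.** p_j = q_j = 0.99 for all raters. Any start in
  (0.5, 1) reaches the same fixed point on our test cases.
* **Numerics.** The E-step runs in the log domain with probabilities
  clamped to [1e-7, 1−1e-7]; the observed-data log-likelihood is recorded
  each iteration and asserted non-decreasing in tests.
* **Degenerate inputs.** Unanimous constant masks (no foreground anywhere,
  or foreground everywhere) short-circuit with a warning; a single rater
  converges to that rater's own mask.

Because the above constants are conventions rather than published values,
bit-exact equality with any particular reference fusion is not guaranteed;
tests instead require object-level F1 ≥ 0.99 against an independent
implementation (SimpleITK) over seeded rater sets — in practice the two
agree pixel-perfectly on those fixtures.

The binarized consensus uses strict W > 0.5, then 8-connected component
labeling and the dataset's minimum object size.

## Object-level similarity and agreement

Objects are maximal 8-connected components. Pairwise IoU feeds a
Hungarian assignment maximizing total IoU; zero-IoU pairings are never
emitted. Mean IoU averages the matched pairs only (NA when nothing
overlaps). Detection counts a matched pair as TP only when IoU > t
strictly — a pair at exactly t is FN + FP — with t = 0.5 by default.
Conventions for empty masks: empty vs empty scores 1, non-empty vs empty
scores 0.

Fleiss' κ needs a universe of "unique objects" across d raters, which is
under-determined by pairwise matching. We match every rater pair at
IoU > t and merge matches transitively (union-find); if a cluster ends up
with two ROIs of one rater, the better-agreeing one stays and the other
becomes its own row. Each row counts raters voting foreground
(n_i1) vs background (n_i0 = d − n_i1). Chance agreement is estimated
over absent objects too: background proposals — squares of median object
area, rejection-sampled (seeded, ≤ 1000 attempts) to be disjoint from all
rater ROIs — are appended as unanimous-background rows, one per unique
object by default. κ = (P̄ − P̄e)/(1 − P̄e) with
P_i = Σ_j n_ij(n_ij−1)/(d(d−1)) summed over both classes and
P̄e = Σ_j p_j². Because the number and placement of proposals and the
clustering rule are package conventions, κ values are comparable within
this package, not across tools.

## U-Net, weighted loss, training

**Architecture.** `depth` counts encoder convolutional modules including
the unpooled bottleneck; the full-scale profile is depth 5 with base 64
filters. Each module is two unpadded 3×3 convolutions with leaky ReLU
(leak 0.1); all but the bottleneck end in 2×2 stride-2 max-pooling. The
decoder mirrors this with 2×2 transposed convolutions, center-cropped
skip concatenation and two 3×3 convolutions; batch normalization follows
every (up-)convolution below the first level, leaving one unnormalized
path so absolute intensities remain visible to the output. A 1×1
convolution yields two-class scores. Valid convolutions make the output
tile smaller than the input (540 → 356 at depth 5); construction fails
loudly, naming the first offending level, if a pooled size turns odd.
Weights are drawn from a truncated normal (±2 std) with He fan-in scale —
the published description names the distribution but not its scale, so
the scale is our documented choice.

**Backend.** The network and its training loop are written directly on
numpy (explicit forward/backward per layer, verified against finite
differences in float64), so the whole pipeline runs and is tested on a
single CPU. There is no GPU path.

**Loss.** Weighted softmax cross entropy, computed from raw scores in
log-sum-exp form and summed over the output tile. The weight map is
w = w_bal + λ·w_sep with

* w_bal = 1 on foreground, v_bal + (1−v_bal)·exp(−d1²/2σ²_bal) on
  background,
* w_sep = exp(−(d1+d2)²/2σ²_sep),

where d1/d2 are Euclidean distances to the nearest and second-nearest
object *by identity* (per-object distance transforms, two smallest).
Defaults λ = 50, v_bal = 0.1, σ_bal = 10, σ_sep = 6. With fewer than two
objects, d2 = ∞ and w_sep vanishes (warned).

**Tiling and augmentation.** Mirror padding by the context margin
(in − out)/2, out-tiles stitched on a grid with edge tiles re-anchored,
so any image size is processable and constant inputs produce seamless
constant outputs. Augmentation applies one geometric transform —
horizontal/vertical flips, right-angle rotation, and an elastic
deformation from a Gaussian-smoothed random displacement field
(field σ = 8 px, magnitude 5 px by default) — identically to image,
target (nearest-neighbor) and weight map, deterministically per seed.
Near tile borders the mirror boundary condition can duplicate objects
into the frame; this is inherent to mirrored augmentation and harmless
for training.

**Optimization.** Adam, mini-batch 4, one-cycle schedule: linear warm-up
from lr_min to lr_max over the first 30% of iterations, cosine anneal
back to lr_min (the policy's shape parameters are not published; this is
our fixed choice). Default lr_max = 4e-4, lr_min = 4e-5, 972 iterations
at full scale. A learning-rate finder is not implemented: the printed
rates fully determine the runs. An epoch is one pass over the training
tiles; a full weight snapshot (checkpoint) is taken per epoch, or per
`checkpoint_every` iterations.

**Selection and ensembling.** The checkpoint with the highest validation
median F1 (t = 0.5) is selected, ties to the later checkpoint. A selected
model must additionally match the worst human expert's F1 against est. GT
on every validation image (expert floor); failing models are flagged and
retained but should not feed biological conclusions. k models from a
k-fold split (stratified by experimental group when known, else random)
form an ensemble predicting by softmax averaging; k = 1 degenerates to a
single model validated on its own training data. Transfer variants:
`from_scratch` (random init), `fine_tuned` (pretrained init, then
training), `frozen` (pretrained weights, zero gradient updates —
asserted bit-identical).

**Profiles.** The full profile (depth 5, base 64, tiles 540/356, 972
iterations) is retained for large runs. The package's test profile is
`mini` — depth 3, base 16 filters, tiles 140/100, 300 iterations — the
problem size at which the training-dependent tests run; a depth-2
"micro" variant (52/36) is used where four folds must train inside a
unit test. These sizes are the package's documented CPU test
configuration, chosen so a full training run memorizes small synthetic
scenes.

## Quantification and statistics

Per image: objects whose centroid lies inside the analysis region are
counted (a border-straddling object is counted exactly once);
density = count / region area, with area = pixels/(px_per_µm²·10⁶) mm².
Mean intensity averages the per-object mean pixel intensities of counted
objects — not pooled pixels; the pooled variant is available by flag
since the verbal definition is ambiguous. Densities can be normalized to
a control group's mean (control mean maps to exactly 1).

Grubbs' two-sided single-outlier test is applied iteratively and only
*flags* indices — exclusion remains an expert decision. Two groups:
Mann-Whitney U (midranks; exact p for small tie-free samples, otherwise
tie-corrected normal approximation). Three or more: Kruskal-Wallis
omnibus, then all pairwise Mann-Whitney tests with Bonferroni
p_adj = min(1, m·p). Effect size uses the uncorrected
Z = (U − n₁n₂/2)/√(n₁n₂(n₁+n₂+1)/12) and η² = Z²/(n₁+n₂) — deliberately
without tie correction, matching the printed effect-size recipe even
though the p-value path is tie-corrected; both are reported so the
discrepancy stays visible. Critical η²(α) = χ²₁(1−α/m)/(n₁+n₂).

Reliability over repeated analyses (strategy × model × comparison):

* *variation per effect* — sample std of η² across a strategy's models,
  per comparison;
* *majority vote* — the outcome (significant at adjusted p ≤ α, with the
  direction of the mean difference) reported by most models across all
  strategies; ties are undecided and excluded;
* *variation per model* — std across comparisons of centered η²
  (η² minus the across-model mean for that comparison within the
  strategy; "centered" is not defined in the source recipe, and this
  centering makes spreads comparable across effects of different size),
  plus the model's count of majority-vote deviations.

## Synthetic data: what it emulates, and what it does not

Scenes are isotropic Gaussian-profile blobs (peak amplitude sampled per
object, half-maximum radius = truth radius) on a constant background with
additive Gaussian noise, clipped to the bit depth. Defaults emulate the
motivating imaging regime scaled to desk size: 256×256 px, 35 objects,
radius 4–8 px, amplitudes 40–120 over background 20 with noise σ = 8
(8-bit), 1.61 px/µm. Simulated annotators detect each object with a
logistic probability in its mean intensity (so dim objects are missed
more, reproducing the observed intensity-dependence of inter-rater
disagreement), jitter boundaries via a smooth perturbation of the signed
distance function, carry a constant dilation/erosion bias, and add
Poisson-distributed dim false positives. `default_annotator_panel` fixes
a three-expert panel (midpoint 20, width 8, jitter 2 px, 2 FP/image,
biases −0.5/0/+0.5) used throughout the tests. Simulated predictors are
convex mixtures of the blurred truth and a correlated noise field
(mixing weight 1 − quality), standing in for trained networks where
statistics, not segmentation, are under test; their noise amplitude was
set so that quality spans the useless-to-perfect range and independent
predictors disagree at the object-count level, which is what the
reliability analysis consumes. Two-group experiments draw per-image
object counts as Poisson(multiplier · base count).

What passing these tests shows: the algorithms behave as specified under
controlled noise — STAPLE recovers known rater parameters, consensus
outperforms individual noisy raters, ensembling reduces effect-size
spread, the network can fit its targets. What they do not show: real
nuclei are not Gaussian blobs (no PSF, shot noise, clustering, tissue
autofluorescence), real experts are not conditionally independent given
the truth, and desk-scale training says nothing about full-scale
generalization to held-out microscopy data.

## Numerical conventions and degenerate cases

* Strict inequalities: consensus binarization W > threshold; detection
  TP at IoU > t.
* 0/0 scores: empty vs empty → 1; non-empty vs empty → 0; Mean IoU with
  no overlapping pair → NaN.
* Checkpoint-selection ties → later checkpoint.
* Grubbs with zero variance or n < 3 → no flags / error.
* κ with P̄e = 1 → 1 if P̄ = 1 else NaN with warning.
* All generators and the training loop are deterministic under their
  seeds (single-threaded CPU).

## Known limitations

* STAPLE is binary with a spatially uniform prior; no multi-class
  fusion or spatially varying priors.
* κ has no variance estimate; no weighted κ.
* The numpy backend is CPU-bound; full-scale (depth-5, 972-iteration)
  training is supported but slow, and no pretrained full-scale weights
  ship with the package.
* Mean-intensity and in-region conventions (per-object means, centroid
  rule) are fixed choices among defensible alternatives; both are
  documented and one is flag-switchable.
* 2-D only: z-stacks must be projected (a maximum-intensity projection
  utility is provided); no colocalization, no proprietary microscope
  formats.
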