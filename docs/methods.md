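# Methods

This note documents the model as implemented: its assumptions, the
parameters that matter, the numerical choices at the points where the
design was genuinely open, and what the synthetic-data generators do and
do not establish.

## Pipeline overview

An input RGB image (float, [0, 1]) is processed by two independent
branches and fused:

1. **Adaptive sparse branch** (`sparse.py`) — resize to 80×60, dense
   5×5 patches at stride 1 over all three channels (d = 75), per-image
   complete FastICA dictionary, patches encoded as sparse coefficient
   vectors, scored by CSD, assembled to a map.
2. **Covariance branch** (`covariance.py`) — resize to 512×512,
   non-overlapping tilings at patch sizes {8, 16, 32, 64, 128}, per-tile
   (mean, covariance) of the 5-dim (R, G, B, x, y) pixel features,
   sigma-point embedding to a 55-vector, scored by CSD; the five scale
   maps are min-max normalized and averaged.
3. **Fusion** (`csd.py`) — the sparse map is bilinearly resized to the
   covariance map's resolution, the maps are multiplied elementwise,
   normalized, Gaussian-smoothed (σ = 0.04 × width, reflective
   boundaries), resized to the input's native resolution and normalized.

## The CSD operator

`csd_scores` implements

    S_i = (1 / (n - 1)) * Σ_{j≠i} ||α_i − α_j||_1 / (1 + ||X_i − X_j||_2)

with patch centers normalized per axis to [0, 1], so the `+1` in the
denominator is resolution-free.  The surround is *all* other patches;
locality comes entirely from the 1/(1 + dist) weight.  We read the
dissimilarity as a ratio (feature difference damped by distance) rather
than a sum of the two terms: an additive distance term would make far,
identical patches "dissimilar", inverting the center–surround logic in
which weights decay with distance.  The vectorized implementation (L1
and L2 pairwise blocks via `scipy.spatial.distance.cdist`, 128-row
chunks) is pinned to a brute-force double-loop oracle at 1e−10.

## Sparse branch

* **Color patches.** ICA operates on full RGB patch vectors (d = 75),
  not grayscale; color singletons must be visible to this branch too.
* **Complete dictionary.** m′ = d by default, making encoding
  invertible (W·A = I to < 1e−6) and the representation lossless.  This
  is the operational content of "adaptive beats fixed": an
  under-complete dictionary learned from *other* images leaves a
  strictly positive residual, and the residual concentrates on what is
  atypical — often the salient content.
* **FastICA settings.** Symmetric (parallel) updates, logcosh/tanh
  contrast, unit-variance whitening, tol 1e−4, max 300 iterations, up
  to 3 restarts with incremented seeds; after that the PCA whitening
  basis is used and `converged=False` is recorded.  On images with
  genuine sparse structure (occlusion edges) FastICA converges in tens
  of iterations; on pure Gaussian noise it cannot converge, because no
  independent non-Gaussian components exist — the whitening fallback
  keeps the pipeline total.
* **Centering** is per dimension across the image's patches; the
  dictionary stores the means and reconstruction restores them.
* **Rank handling.** Components are reduced to the numerical rank of
  the centered patch matrix; a patch matrix that is constant up to
  round-off (peak-to-peak ≤ 1e−12) raises a degenerate-dictionary
  error, which `sparse_saliency_map` maps to an all-zero map with a
  warning, and the full model then returns the smoothed covariance
  branch alone.
* **Scales.** Default is the single 80×60 scale.  `scales=2,3` adds
  ×0.5 and ×2 working resolutions whose maps are combined by the
  normalized product (`multiscale_combine`); this mode is provided but
  has no canonical parameterization.

## Covariance branch

* **Features.** (R, G, B, x, y) only — no gradients or orientation
  planes.  Orientation sensitivity is deliberately delegated to the
  sparse branch, whose adaptive bases are Gabor-like.
* **Unbiased covariance** (divisor m − 1) per tile; feature dimensions
  that are constant within a tile contribute exactly zero (explicitly
  flushed, so a featureless region scores exactly 0 rather than 1e−32).
* **Sigma-point embedding.** With C = L·Lᵀ (Cholesky after a diagonal
  jitter of 1e−10 · trace/d, escalated ×10 up to 3 times), the
  embedding is ψ = (μ, μ + √d·l_1 … μ + √d·l_d, μ − √d·l_1 … μ − √d·l_d),
  length (2d+1)·d = 55.  The √d scaling makes the biased covariance of
  the 2d offset points reproduce C exactly (pinned at 1e−8 over random
  PSD matrices); the first block is μ.  A zero covariance embeds as μ
  repeated 2d + 1 times.
* **Patch-local coordinates (default).**  The x, y planes are
  normalized within each tile, so two identical textures anywhere in
  the image have identical descriptors and a constant image yields an
  exactly zero map.  The alternative (`coordinate_mode="global"`)
  normalizes coordinates over the whole image, which adds an explicit
  spatial term to the descriptor itself; we default to local because
  the CSD weight already encodes inter-patch distance and a second,
  implicit spatial term would make even featureless images produce
  structured saliency.  A regression test pins the dichotomy.
* **Tiling.** Non-overlapping tiles (512 is divisible by every patch
  size); this keeps each scale at ≤ 4096 patches and needs no stride
  convention.
* **Scale combination: average, not product.**  Each scale's map is
  min-max normalized and the five maps are averaged.  A product lets
  any one scale's multiplicative noise (or its forced zero at the
  per-scale minimum) veto all other scales; empirically the product
  reading destroys orientation pop-out, which the fused model should
  and does detect (it is carried by the sparse branch and must survive
  fusion).  The normalized-product combiner remains available as
  `multiscale_combine` and is what the sparse multiscale mode uses.

## Fusion and smoothing

The sparse map is resized *before* the multiplication (the only
dimensionally consistent order given the branch resolutions).  The final
Gaussian σ is expressed as a fraction of map width; the default 0.04
lies in the range this model family reports as optimal for fixation
prediction, and `sigma_sweep` lets users re-optimize it on their own
data.  Smoothing uses reflective boundaries; σ = 0 is the identity.  All returned maps are min-max normalized to [0, 1]; a
constant map normalizes to all-zeros if the constant is 0, else to
all-ones (this keeps "no signal" distinguishable from "uniform
signal" and makes normalization idempotent).

## Evaluation metrics

* `rank_auc` is the Mann–Whitney statistic (ties = ½), computed from
  rank sums; equal to trapezoidal ROC AUC and pinned to exhaustive pair
  counting at 1e−12.
* `shuffled_auc` samples, per repetition, as many negatives as there
  are positives from the other-image fixation pool — without
  replacement when the pool allows — and averages over 20 repetitions
  by default.  Saliency is read by nearest-pixel lookup; duplicate
  fixations are kept (the statistic is rank-based).  A constant map
  scores exactly 0.5.
* `dsc_curve` thresholds at 256 uniform levels in [0, 1]; DSC is
  defined 0 when both sets are empty; PoDSC is the lattice maximum.
* `sigma_sweep` re-smooths an unsmoothed map at each σ and reports the
  argmax σ alongside the scores; the metric is supplied as a closure so
  the same sweep drives sAUC, AUC, or PoDSC.

## Synthetic data

* **Pop-out displays** (`generate_pattern`): eight kinds — color,
  orientation, conjunction, curvature, intersection (junction),
  symmetry, size singletons, and a dense-texture oddball.  Items are
  bars of 3:1 aspect (length 0.6 of a grid cell) on a 6×6 grid in a
  256×256 mid-gray frame with ±0.15-cell center jitter; red target /
  green distractors for the color kind, green otherwise.  The mask is
  the target item's bounding region (pixel bounding box united with a
  cell-sized box at its center).  A control render
  (`paint_target=False`) paints the target cell as one more distractor
  with an identical random stream, enabling render-and-diff tests.
* **Center-biased fixations** (`generate_center_bias_fixations`):
  isotropic Gaussian at the frame center, σ = 0.2 × width by default,
  rejection-sampled into bounds, identical distribution across images —
  precisely the bias structure shuffled AUC is designed to cancel.
* **Natural-statistics images** (`natural_image`): a dead-leaves model
  (occluding disks, power-law radii), giving scale-invariant structure,
  sharp occlusion edges and heavy-tailed filter statistics — the regime
  where ICA bases become Gabor-like and codes leptokurtic (measured
  excess kurtosis ≈ +13 on 5×5 patch codes).

What passing tests on these stimuli show: the pipeline's operators are
correct against oracles, the fused model detects color and orientation
singletons (≥ 9/10 seeded displays each), and the evaluation stack is
unbiased under shared center bias.  What they do not show: performance
on photographs — real scenes have textures, lighting, semantics and
higher-order dependencies no generator here emulates, and dataset-level
fixation scores require the actual eye-tracking corpora, for which
generic readers (`read_fixations`, with a configurable coordinate
origin, since annotation conventions vary) are provided.

## Problem sizes and determinism

The test suite and acceptance script run everything at the model's
native working resolutions (80×60 sparse, 512×512 covariance); the
chance-level experiment uses 50 images × 20 fixations × 20 repetitions.
A full-model run takes a couple of seconds on one core.  All
stochasticity (ICA initialization, negative resampling, stimulus
geometry) flows through explicit integer seeds; fixed seed and input
give byte-identical maps.

## Known limitations

* The covariance branch is blind to pure orientation differences by
  construction; conjunction and texture-density oddballs are found
  unreliably (consistent with conjunction search being inefficient in
  human observers, but not a validated claim of this implementation).
* Symmetry singletons are detected weakly: the CSD operator compares
  whole-item feature vectors and has no explicit axial-symmetry
  detector.
* The whole-image surround (w = n − 1) with 1/(1 + dist) weighting
  mildly favors central patches over corner patches — an operator
  property, not an added center-bias prior; no explicit or implicit
  center bias is ever added.
* FastICA non-convergence falls back to the whitening basis, which
  preserves losslessness but not sparsity of codes; `converged` records
  this.
* Video/motion channels and top-down (goal-driven) modulation are out
  of scope.
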