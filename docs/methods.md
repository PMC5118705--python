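# Methods

## The descriptor

`collagetex` computes a per-pixel (or per-voxel) texture map that measures
the *disorder of dominant gradient orientations* in a lesion, and collapses
it into a fixed-length feature vector for classification.

For a scene `C` with intensity `f(c)` and a binary region of interest
(ROI):

1. **Gradients.** `∂f_X`, `∂f_Y` (and `∂f_Z` in 3D) are central
   differences per axis, `(f[i+1] − f[i−1]) / 2`, with out-of-range
   samples supplied by replicate (default) or reflect padding.  No
   smoothing is applied; gradients are in grid units (physical spacing is
   recorded but not used to rescale them).
2. **Dominant orientation.** For every location, the gradient vectors of
   its `(2r+1)`-wide window are stacked into a matrix `G` (raster order)
   and the first right singular vector `ψ` of `G` is taken — equivalently
   the top eigenvector of the window's structure tensor `GᵀG`, the unit
   direction maximizing `Σ_k (g_k · u)²`.  In 2D this gives
   `θ = atan2(ψ_Y, ψ_X)`; in 3D additionally
   `φ = atan2(ψ_Z, √(ψ_X² + ψ_Y²))`.
3. **Discretization.** `θ ∈ (−π, π]` is mapped to `B` equal bins of width
   `ω = 2π/B` via `⌊(θ+π)/ω⌋`, with the single point `θ = π` clamped into
   bin `B−1`; `φ ∈ [−π/2, π/2]` is binned analogously with width `π/B`.
4. **Co-occurrence and entropy.** For every ROI location, the binned
   orientations of its window are paired at the unit-displacement
   directions (4 unique directions in 2D, 13 in 3D, counted symmetrically
   so the `B×B` matrix equals its transpose), and the Shannon entropy in
   bits of the normalized matrix, `ε = −Σ m log₂ m` with `0·log 0 := 0`,
   becomes the location's value.  `ε` is bounded by `log₂(B²)`.
5. **Feature vector.** The entropy histogram over the *fixed* range
   `[0, log₂(B²)]` with `v` equal bins (rightmost closed), normalized to
   frequencies.  In 3D, the `v×v` joint histogram of the azimuth and
   elevation maps, flattened row-major.

The scientific premise: architecturally disordered (aggressive) tissue
has locally incoherent gradient fields, spreading co-occurrence mass over
many orientation-pair cells and driving `ε` up; coherent (benign)
micro-architecture concentrates it.

## Conventions that were genuinely open, and why these were chosen

* **Sign of the singular vector.**  `ψ` and `−ψ` are interchangeable for
  SVD; we orient `ψ` to have nonnegative dot product with the window's
  summed gradient, with deterministic tie-breaks (`ψ_X ≥ 0`, then
  `ψ_Y ≥ 0`, then `ψ_Z ≥ 0`), and negative zeros cleared so
  `atan2(0, 0) = 0`.  This keeps `θ` sensitive to contrast polarity — a
  bright-on-dark edge and its inversion get opposite orientations — which
  is what lets the descriptor distinguish a checkerboard from its
  intensity complement while gray-level co-occurrence statistics cannot.
* **Angle range.**  The full signed range `(−π, π]` rather than the
  folded `[0, π)`: folding would erase exactly the inversion sensitivity
  above.  A consequence worth knowing: a *global* intensity inversion
  shifts every non-degenerate orientation by π, which merely permutes
  co-occurrence bins; observable map differences between an image and its
  complement come from sign-rule ties and degenerate (zero-gradient)
  windows, which do not flip.
* **Co-occurrence pairing.**  All unit-displacement neighbor pairs inside
  the window, mirroring the classical gray-level co-occurrence
  convention.  This offset set is closed under 90° rotation, which gives
  the map exact quarter-turn equivariance (for `B` divisible by 4) at
  pixels whose windows avoid boundary padding — a property the test suite
  asserts.
* **Orientation bins.**  `B = 64` by default (`ω < 6°`), configurable.
* **ROI margin.**  Orientations are computed on the grid extended by the
  window radius, using real image context outside the ROI where it
  exists; padding enters only at image borders.  Only ROI locations
  receive an entropy value or enter the histogram, so lesion-boundary
  pixels are not dominated by padding artifacts.
* **Histogram range.**  Fixed at `[0, log₂(B²)]` rather than per-image
  min/max, so feature vectors are comparable across lesions; frequencies
  rather than counts, so they are invariant to lesion size.
* **Degenerate windows** (all-zero gradients): flagged, assigned `θ = 0`
  (hence a well-defined bin), so constant scenes yield exactly-zero
  entropy maps and the point-mass histogram `(1, 0, …, 0)`.
* **Entropy base.**  Base-2 logarithm of the normalized matrix (bits).
* **Optional ROI rescaling** before gradient computation is exposed as a
  config flag (`rescale_roi`), default off; intensity standardization for
  real multi-scanner data is deliberately out of scope and can be applied
  upstream.

## Baseline banks

* **Haralick (52 features):** 13 classical second-order statistics of the
  symmetric distance-1 gray-level co-occurrence matrix (averaged over the
  four directions 0°/45°/90°/135°), computed per pixel over each of 4
  window sizes `{3, 5, 7, 9}` and aggregated per lesion by the median.
  Intensities are quantized to 64 levels on the ROI range, which makes
  the statistics invariant to adding a constant to the image.  Degenerate
  denominators (zero variance, zero marginal entropy) yield 0 for the
  affected statistic.
* **Gabor (432 filters):** the Cartesian product of 6 spatial
  frequencies, 8 orientations (multiples of 22.5°) and 9 envelope sigmas
  `{1, 1.5, …, 5}` px.  Each complex filter is convolved with the image
  (replicate boundaries); the per-pixel response magnitude
  `√(real² + imag²)` is median-aggregated over the ROI.
* **HOG:** a single ROI-level histogram of signed per-pixel gradient
  orientations over 360°, `v ∈ {10, 15, 20, 25, 30}` bins (bin width
  `360°/v`), magnitude-weighted and normalized — not the detector-style
  block-normalized layout, since the ROI is a single lesion.  The bank's
  declared total in size arithmetic is kept at the conventional round 100
  (the five `v` settings themselves contribute 90 histogram bins).

## Evaluation protocol

Samples are ROIs; every sample carries a patient `group_id`.  Fold
assignment shuffles *patients* and deals them round-robin into `k = 3`
folds, so no patient straddles training and testing.  Per iteration a
fresh grouped split is drawn and a 50-tree random forest (`√d` features
per split, unlimited depth, seeded per iteration from the master seed) is
trained on two folds and scored on the third; `β_acc` is the mean
held-out accuracy over all iteration-fold pairs, in percent, reported
with its standard deviation.  Probability scores are the fraction of
trees voting positive; the accuracy operating point is the majority vote.
Splits that leave a training side single-class are resampled (bounded
retries).  ROC AUC uses the tie-aware all-pairs definition.  Rank-sum
comparisons use mid-ranks, an exact null for small tie-free samples and
the tie-corrected normal approximation (no continuity correction)
otherwise; multiple comparisons are adjusted by Holm step-down
(Bonferroni available).

**Chance-level control.**  `label_permuted_control` redraws patient
labels *independently* (fair coin per patient, fresh draw every
iteration) rather than applying one exactly balanced permutation.  With
balanced relabeling under grouped CV on clustered features, the held-out
fold's class imbalance is anti-correlated with the training folds',
biasing the control well below 50% (the anti-learning artifact; single
permutations measured as low as ~25% on a separable cohort).  Independent
relabeling makes the no-association null exact, and the control
concentrates at 50%.

## The phantom generator

`make_oriented_texture` renders a sinusoidal carrier
`A/2 (1 + sin(2π(r sinα + c cosα)/λ))`, `A = 255`, `λ = 8` px by default,
whose orientation `α` is perturbed once per `patch × patch` block
(default 6 px — at the window scale the descriptor probes, not per pixel)
by zero-mean Gaussian jitter of standard deviation σ, plus additive
Gaussian noise (σ = 2 intensity units).  The 3D variant jitters azimuth
and elevation per cubic patch.  Cohorts assign one unique group id per
phantom patient, centered elliptical masks strictly inside the frame (so
boundary padding never dominates), labels ±1, and per-scene seeds spawned
from a master seed; regeneration is bit-identical.

What the phantoms emulate: a class contrast carried *only* by local
orientation disorder, with patient grouping for leakage-free CV.  What
they do not emulate: MRI/CT physics, bias fields, intensity
non-stationarity, partial-volume effects, anisotropic voxels, or
realistic lesion shapes.  Passing the cohort-discrimination check
therefore shows that the implementation chain (gradients → SVD →
binning → co-occurrence → entropy → histogram → grouped CV) transmits an
orientation-disorder signal end to end; it says nothing about accuracy on
clinical cohorts.

## Problem sizes and numerical checks

The test suite verifies the optimized maps bit-for-bit against a naive
per-pixel reimplementation on 20 random scenes (2D up to 32×32, 3D up to
12×12×6; window radii 1–2; `B ∈ {16, 64}`), fuzzes the entropy bounds,
and asserts the rotation-equivariance, checkerboard-complement, and
chance-control properties above.  The cohort-discrimination check uses 20
phantom patients per class at 48×48 with a 45° jitter gap, `v = 10`, 5×5
windows, 50 trees, and 25 CV iterations — a deliberately compact version
of the repeated-CV protocol that keeps the whole suite fast while leaving
the statistics stable (accuracy saturates at 100% with the control at
50 ± 3%).

Exact-equality testing is possible because implementation and oracle
share only the mathematical definition and the underlying LAPACK/libm
primitives: batched SVD equals per-matrix SVD, and entropy sums are
accumulated over identically ordered nonzero cells.

## Known limitations

* Anisotropic voxel spacing is recorded but not applied to gradients;
  strongly anisotropic volumes should be resampled upstream (the 3D maps
  are qualitative in that regime).
* Per-pixel windowed Haralick extraction is `O(|ROI| · levels²)` per
  window size and is the slowest bank on large lesions.
* The `v × v` joint 3D histogram grows quadratically in `v`; for small
  ROIs most cells are empty and a classifier may prefer the 2D marginal.
* The rank-sum exact null requires tie-free data; accuracy series with
  many repeated values fall back to the tie-corrected approximation.
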