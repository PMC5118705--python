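# collagetex

Radiomic texture maps from the **co-occurrence of local anisotropic
gradient orientations** (CoLlAGe), for distinguishing disease phenotypes
that look alike on anatomic imaging — e.g. radiation necrosis vs recurrent
brain tumor on MRI, or granuloma vs adenocarcinoma on CT — where the
discriminating signal is the *disorder of tissue micro-architecture*
rather than gray-level statistics.

It is written for imaging researchers who have a 2D image or 3D volume
plus a lesion mask and want per-pixel entropy maps, lesion-level feature
vectors, baseline texture banks, and a leakage-free evaluation protocol,
all scriptable from Python (a thin CLI is included).

## The descriptor

For every ROI location `c`:

1. compute intensity gradients `∂f_X, ∂f_Y (, ∂f_Z)` by central
   differences;
2. stack the gradient vectors of the `(2r+1)`-wide window around `c` into
   a matrix `G` and take its first right singular vector `ψ` — the
   dominant local gradient orientation, `θ = atan2(ψ_Y, ψ_X)` (and
   elevation `φ = atan2(ψ_Z, √(ψ_X²+ψ_Y²))` in 3D);
3. discretize orientations into `B` equal bins (`ω = 2π/B`), build the
   `B×B` co-occurrence matrix of binned orientations over the window, and
   assign `c` the Shannon entropy `ε(c) = −Σ m log₂ m` of the normalized
   matrix.

The lesion-level feature vector `F` is the `v`-bin histogram of `ε` over
the fixed range `[0, log₂ B²]` (a `v×v` joint histogram of the azimuth and
elevation maps in 3D).  Disordered micro-architecture → incoherent local
gradient orientations → high `ε`.

Also included: Haralick (13 statistics × 4 window sizes), Gabor
(6 frequencies × 8 orientations × 9 sigmas = 432 filters) and HOG
(`v ∈ {10,15,20,25,30}`, bin width `360°/v`) baseline banks with median
lesion aggregation; patient-grouped 3-fold random-forest cross-validation
(`β_acc` over repeated iterations), ROC/AUC, rank-sum comparisons with
Holm correction, a parameter-sensitivity sweep; and a seeded phantom
generator whose classes differ in local orientation jitter.

## Worked example

```python
from collagetex import (CollageConfig, PhantomSpec, collage_entropy_map_2d,
                        elliptical_mask, make_oriented_texture)

config = CollageConfig(window_radius=2, orientation_bins=64)
for name, jitter in [("coherent", 0.0), ("disordered", 45.0)]:
    scene = make_oriented_texture(PhantomSpec(shape=(48, 48),
                                              jitter_deg=jitter, seed=3))
    emap = collage_entropy_map_2d(scene, elliptical_mask((48, 48)), config)
    eps = emap.roi_values
    print(f"{name}: mean entropy {eps.mean():.3f} bits,"
          f" range [{eps.min():.3f}, {eps.max():.3f}]")
```

prints

```
coherent: mean entropy 1.421 bits, range [0.961, 1.761]
disordered: mean entropy 5.467 bits, range [2.290, 7.170]
```

— the coherent texture concentrates orientation co-occurrences in a few
bins (low entropy), while 45° of local orientation jitter spreads them
(mean `ε` rises by ~4 bits; the ceiling at `B = 64` is `log₂ 64² = 12`).
Pushing those feature vectors through grouped 3-fold RF cross-validation
(`examples/04_cohort_classification.py`) separates the classes at
`β_acc = 100.00 ± 0.00 %` with the label-permuted control at `46.03 %`
(chance).  The `examples/` directory has one short script per capability:
entropy maps and heat-map export, 3D joint features, the
checkerboard-vs-complement contrast, cohort classification, and the
(window, v) sensitivity surface.

Command line, equivalently:

```sh
collagetex synth --cohort 4 --seed 1 --out d/
collagetex extract --image d/patient_0_000_slice0.tiff \
    --mask d/patient_0_000_slice0_mask.tiff --window 5 --bins 64 \
    --hist-bins 10 --heatmap hm.png
```

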