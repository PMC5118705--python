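"""Why signed gradient orientations matter: a checkerboard vs its complement.

Gray-level co-occurrence (Haralick) statistics of a binary checkerboard
are blind to intensity inversion — complementing the image merely relabels
the two gray levels, permuting the co-occurrence matrix without changing
its entropy.  The orientation-entropy map is not blind: inversion flips
gradient signs, and the deterministic sign convention for the dominant
axis resolves ties and degenerate windows differently in the two images.
"""

import numpy as np

from collagetex import (
    BaselineConfig,
    CollageConfig,
    ROIMask,
    collage_entropy_map_2d,
    haralick_feature_map,
    make_checkerboard_pair,
)

n, cell = 24, 3
p1, p2 = make_checkerboard_pair(cell, (n, n))
assert np.all(p1.intensities + p2.intensities == 255.0)

mask = np.zeros((n, n), bool)
mask[4 : n - 4, 4 : n - 4] = True

cfg = CollageConfig(window_radius=1, orientation_bins=64)
m1 = collage_entropy_map_2d(p1, ROIMask(mask), cfg)
m2 = collage_entropy_map_2d(p2, ROIMask(mask), cfg)
d = np.abs(m1.roi_values - m2.roi_values)
print(f"orientation-entropy maps: max difference {d.max():.3f} bits "
      f"({(d > 1e-9).sum()}/{d.size} ROI pixels differ)")

bc = BaselineConfig(haralick_window_sizes=(5,), haralick_levels=2)
maps1, _ = haralick_feature_map(p1, ROIMask(mask), bc)
maps2, _ = haralick_feature_map(p2, ROIMask(mask), bc)
hd = np.abs(maps1[8][mask] - maps2[8][mask])  # entropy statistic
print(f"gray-level co-occurrence entropy maps: max difference {hd.max():.2e}")
print("=> the orientation descriptor separates the pair; Haralick cannot")
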