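"""Full pipeline: phantom cohort -> feature vectors -> grouped RF CV.

Generates a two-class cohort of 10 phantom "patients" per class whose
classes differ only in local orientation disorder (0 vs 45 degrees of
per-patch jitter), extracts 10-bin entropy-histogram feature vectors, and
runs patient-grouped 3-fold random-forest cross-validation (50 trees).

Printed numbers: beta_acc is the mean held-out accuracy (in percent) over
all iteration-fold pairs; the permuted control destroys the feature-label
link and should sit near 50 percent; the AUC uses the mean out-of-fold
probability scores.  The rank-sum comparison tests the CoLlAGe accuracy
series against a HOG baseline computed on the same cohort — on a cohort
this well separated both descriptors saturate and the test correctly
reports no difference (adjusted p = 1); on harder contrasts it
discriminates.
"""

import numpy as np

from collagetex import (
    CollageConfig,
    CVConfig,
    PhantomSpec,
    Sample,
    extract_collage_feature_vector,
    hog_feature_vector,
    label_permuted_control,
    make_phantom_cohort,
    rf_cross_validate,
    roc_auc,
    wilcoxon_compare,
)

cohort = make_phantom_cohort(
    10,
    (
        PhantomSpec(shape=(48, 48), jitter_deg=0.0),
        PhantomSpec(shape=(48, 48), jitter_deg=45.0),
    ),
    master_seed=7,
)
cfg = CollageConfig(window_radius=2, orientation_bins=64, hist_bins=10)
cv = CVConfig(folds=3, iterations=10, trees=50, seed=7)

collage = [
    Sample(extract_collage_feature_vector(s, m, cfg).values, l, m.group_id)
    for s, m, l in cohort.samples
]
hog = [
    Sample(hog_feature_vector(s, m, 10).values, l, m.group_id)
    for s, m, l in cohort.samples
]

res = rf_cross_validate(collage, cv)
ctrl = label_permuted_control(collage, cv)
res_hog = rf_cross_validate(hog, cv)

print(f"CoLlAGe beta_acc = {res.beta_acc_mean:.2f} +/- {res.beta_acc_std:.2f} %")
print(f"permuted control = {ctrl.beta_acc_mean:.2f} %  (chance is 50)")
print(f"AUC (out-of-fold scores) = {roc_auc(res.mean_scores, res.labels):.3f}")
print(f"HOG baseline beta_acc = {res_hog.beta_acc_mean:.2f} %")
w, p, p_adj = wilcoxon_compare(
    res.per_iteration_accuracies, res_hog.per_iteration_accuracies,
    n_comparisons=3,
)
print(f"rank-sum CoLlAGe vs HOG: W = {w:.1f}, raw p = {p:.2e}, "
      f"adjusted p = {p_adj:.2e}")
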