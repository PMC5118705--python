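"""Grouped random-forest cross-validation, ROC/AUC, and rank-sum comparisons.

The protocol: repeated 3-fold cross-validation where *fold assignment is by
patient* — every sample sharing a group id lands in exactly one fold, so no
patient contributes to both training and testing.  A 50-tree random forest
is trained on two folds and scored on the third; the average classification
accuracy over all iteration-fold pairs (in percent) is the headline number,
reported with its standard deviation.  Probability scores are the fraction
of trees voting for the positive class; the accuracy operating point is the
majority vote (threshold 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, GroupingError, UndefinedAUCError

__all__ = [
    "Sample",
    "CVConfig",
    "CVResult",
    "samples_from_table",
    "grouped_random_kfold",
    "label_permuted_control",
    "rf_cross_validate",
    "roc_auc",
    "wilcoxon_compare",
    "holm_adjust",
    "parameter_sensitivity_grid",
]


@dataclass
class Sample:
    """One ROI's feature vector with its class label and patient group."""

    features: np.ndarray
    label: int  # +1 or -1
    group_id: str

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.label not in (+1, -1):
            raise ConfigError("label must be +1 or -1")


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation protocol parameters.

    Defaults mirror the evaluation protocol: 3 folds, 150 iterations, 50
    trees, grouping on.  Each iteration reshuffles the grouped folds and
    reseeds the forest from the master seed.
    """

    folds: int = 3
    iterations: int = 150
    trees: int = 50
    seed: int = 0
    grouped: bool = True
    max_retries: int = 20

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ConfigError("folds must be >= 2")
        if self.iterations < 1:
            raise ConfigError("iterations must be >= 1")


@dataclass
class CVResult:
    """Aggregated cross-validation outcome (accuracies in percent)."""

    beta_acc_mean: float
    beta_acc_std: float
    per_iteration_accuracies: np.ndarray  # (iterations,) mean over folds
    per_fold_accuracies: np.ndarray  # (iterations * folds,)
    mean_scores: np.ndarray  # per-sample mean P(+1) over test appearances
    labels: np.ndarray


def samples_from_table(table: pd.DataFrame, feature_prefix: str | None = None) -> list[Sample]:
    """Build samples from a feature table with ``label`` and ``group_id``
    columns; feature columns are all numeric columns not named ``label``
    (or those matching ``feature_prefix``)."""
    if "label" not in table or "group_id" not in table:
        raise ConfigError("table needs 'label' and 'group_id' columns")
    if feature_prefix:
        cols = [c for c in table.columns if c.startswith(feature_prefix)]
    else:
        cols = [
            c
            for c in table.select_dtypes("number").columns
            if c != "label"
        ]
    if not cols:
        raise ConfigError("no feature columns found")
    return [
        Sample(row[cols].to_numpy(dtype=np.float64), int(row["label"]), str(row["group_id"]))
        for _, row in table.iterrows()
    ]


def grouped_random_kfold(
    samples: list[Sample], k: int, seed: int
) -> np.ndarray:
    """Random fold assignment constrained so each group is wholly in one fold.

    Groups are shuffled with the given seed and dealt into ``k`` folds as
    evenly as possible (group counts differ by at most 1).  Deterministic
    for a fixed seed.

    Returns
    -------
    fold : int array, ``fold[i]`` in ``0..k-1`` per sample.
    """
    groups = sorted({s.group_id for s in samples})
    if len(groups) < k:
        raise GroupingError(
            f"{len(groups)} groups cannot fill {k} folds"
        )
    rng = np.random.default_rng(seed)
    order = [groups[i] for i in rng.permutation(len(groups))]
    assignment = {g: i % k for i, g in enumerate(order)}
    return np.array([assignment[s.group_id] for s in samples])


def _forest(trees: int, seed: int):
    from sklearn.ensemble import RandomForestClassifier

    return RandomForestClassifier(
        n_estimators=trees,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )


def rf_cross_validate(samples: list[Sample], config: CVConfig | None = None) -> CVResult:
    """Repeated grouped k-fold cross-validation with a random forest.

    Per iteration: a fresh grouped split; for each fold rotation, a
    ``trees``-tree forest trained on the other folds is scored on the
    held-out fold.  Splits leaving a training side single-class are
    resampled (bounded retries).  ``beta_acc_mean``/``std`` are over all
    iteration-fold accuracies, in percent.
    """
    config = config or CVConfig()
    X = np.stack([s.features for s in samples])
    y = np.array([s.label for s in samples])
    if len(set(y)) < 2:
        raise ConfigError("both classes must be present")
    k = config.folds
    seeds = np.random.SeedSequence(config.seed).generate_state(
        config.iterations * (config.max_retries + 1)
    )
    per_fold = []
    per_iter = []
    score_sum = np.zeros(len(samples))
    score_cnt = np.zeros(len(samples))
    si = 0
    for _ in range(config.iterations):
        for attempt in range(config.max_retries + 1):
            split_seed = int(seeds[si] % (2**31))
            si += 1
            if config.grouped:
                fold = grouped_random_kfold(samples, k, split_seed)
            else:
                rng = np.random.default_rng(split_seed)
                fold = rng.permutation(len(samples)) % k
            ok = all(
                len(set(y[fold != f])) == 2 and np.any(fold == f)
                for f in range(k)
            )
            if ok:
                break
        else:
            raise GroupingError(
                "could not find a split with both classes in every "
                f"training side after {config.max_retries} retries"
            )
        fold_accs = []
        for f in range(k):
            train, test = fold != f, fold == f
            clf = _forest(config.trees, split_seed + f)
            clf.fit(X[train], y[train])
            prob = clf.predict_proba(X[test])
            pos_col = int(np.where(clf.classes_ == 1)[0][0])
            p_pos = prob[:, pos_col]
            pred = np.where(p_pos >= 0.5, 1, -1)
            fold_accs.append(100.0 * float(np.mean(pred == y[test])))
            score_sum[test] += p_pos
            score_cnt[test] += 1
        per_fold.extend(fold_accs)
        per_iter.append(float(np.mean(fold_accs)))
    per_fold = np.array(per_fold)
    mean_scores = np.divide(
        score_sum, score_cnt, out=np.full(len(samples), np.nan),
        where=score_cnt > 0,
    )
    return CVResult(
        beta_acc_mean=float(per_fold.mean()),
        beta_acc_std=float(per_fold.std(ddof=1)),
        per_iteration_accuracies=np.array(per_iter),
        per_fold_accuracies=per_fold,
        mean_scores=mean_scores,
        labels=y,
    )


def label_permuted_control(
    samples: list[Sample], config: CVConfig | None = None
) -> CVResult:
    """Chance-level control: cross-validation with the feature-label link
    destroyed.

    Every iteration redraws patient labels independently (fair coin per
    group, redrawn if a draw leaves one class empty) before the grouped
    split, so the null hypothesis of no association holds exactly and the
    expected accuracy is 50%.  Reusing one fixed balanced permutation
    instead would bias the control *below* chance: with exactly balanced
    relabeling, the held-out fold's class imbalance is anti-correlated
    with the training folds' (the anti-learning artifact of grouped CV on
    clustered features).
    """
    config = config or CVConfig()
    groups = sorted({s.group_id for s in samples})
    seeds = np.random.SeedSequence([config.seed, 0x9E3779B9]).generate_state(
        config.iterations
    )
    one_iter = CVConfig(
        folds=config.folds,
        iterations=1,
        trees=config.trees,
        seed=config.seed,
        grouped=config.grouped,
        max_retries=config.max_retries,
    )
    per_fold = []
    per_iter = []
    score_sum = np.zeros(len(samples))
    score_cnt = np.zeros(len(samples))
    for it in range(config.iterations):
        rng = np.random.default_rng(int(seeds[it]))
        while True:
            flips = rng.integers(0, 2, size=len(groups))
            if 0 < flips.sum() < len(groups):
                break
        lab = {g: (1 if f else -1) for g, f in zip(groups, flips)}
        relabeled = [
            Sample(s.features, lab[s.group_id], s.group_id) for s in samples
        ]
        cfg_it = CVConfig(
            folds=one_iter.folds,
            iterations=1,
            trees=one_iter.trees,
            seed=int(seeds[it] % (2**31)),
            grouped=one_iter.grouped,
            max_retries=one_iter.max_retries,
        )
        res = rf_cross_validate(relabeled, cfg_it)
        per_fold.extend(res.per_fold_accuracies.tolist())
        per_iter.append(float(res.per_fold_accuracies.mean()))
        seen = ~np.isnan(res.mean_scores)
        score_sum[seen] += res.mean_scores[seen]
        score_cnt[seen] += 1
    per_fold = np.array(per_fold)
    mean_scores = np.divide(
        score_sum, score_cnt, out=np.full(len(samples), np.nan),
        where=score_cnt > 0,
    )
    return CVResult(
        beta_acc_mean=float(per_fold.mean()),
        beta_acc_std=float(per_fold.std(ddof=1)),
        per_iteration_accuracies=np.array(per_iter),
        per_fold_accuracies=per_fold,
        mean_scores=mean_scores,
        labels=np.array([s.label for s in samples]),
    )


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve: ``P(score+ > score-) + 0.5 P(tie)`` over
    all positive-negative pairs."""
    from sklearn.metrics import roc_auc_score

    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise UndefinedAUCError("AUC needs both classes present")
    return float(roc_auc_score(labels == labels.max(), scores))


def wilcoxon_compare(
    a, b, n_comparisons: int = 1, method: str = "holm"
) -> tuple[float, float, float]:
    """Two-sided rank-sum comparison of two accuracy series.

    Mid-ranks for ties; exact null when both series are small and tie-free,
    tie-corrected normal approximation otherwise (no continuity
    correction).  The adjusted p applies a ``method`` correction for
    ``n_comparisons`` simultaneous tests (for a single p both Holm and
    Bonferroni reduce to ``min(1, n * p)``).

    Returns
    -------
    (rank-sum statistic of ``a``, raw p, adjusted p)
    """
    from scipy import stats

    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ConfigError("both series must be nonempty")
    if method not in ("holm", "bonferroni"):
        raise ConfigError(f"unknown adjustment {method!r}")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w = float(ranks[: a.size].sum())
    if np.all(pooled == pooled[0]):
        p = 1.0
    else:
        has_ties = len(np.unique(pooled)) < pooled.size
        use_exact = not has_ties and a.size <= 25 and b.size <= 25
        res = stats.mannwhitneyu(
            a,
            b,
            alternative="two-sided",
            method="exact" if use_exact else "asymptotic",
            use_continuity=False,
        )
        p = float(res.pvalue)
    return w, p, min(1.0, n_comparisons * p)


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjustment of a family of p-values (monotone,
    clipped at 1)."""
    p = np.asarray(pvalues, dtype=np.float64)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def parameter_sensitivity_grid(
    cohort,
    window_radii,
    v_grid,
    cv_config: CVConfig | None = None,
    orientation_bins: int = 64,
) -> pd.DataFrame:
    """Classification accuracy over the (window size, histogram bins) grid.

    For every combination, CoLlAGe feature vectors are recomputed for the
    cohort and pushed through grouped RF cross-validation.  Entropy maps
    are computed once per window radius and re-histogrammed per ``v``.

    Parameters
    ----------
    cohort
        Iterable of ``(scene, mask, label)`` tuples (e.g. a
        :class:`~collagetex.phantoms.PhantomCohort`'s samples).

    Returns
    -------
    DataFrame with columns ``window_radius``, ``window_size``, ``v``,
    ``beta_acc_mean``, ``beta_acc_std``.
    """
    from .core import CollageConfig, collage_entropy_map_2d, collage_entropy_maps_3d
    from .features import entropy_histogram, joint_entropy_histogram

    cv_config = cv_config or CVConfig()
    cohort = list(cohort)
    if not window_radii or not v_grid:
        raise ConfigError("parameter grids must be nonempty")
    records = []
    for r in window_radii:
        base = CollageConfig(window_radius=r, orientation_bins=orientation_bins)
        maps = []
        for scene, mask, _label in cohort:
            if scene.dims == 2:
                maps.append((collage_entropy_map_2d(scene, mask, base),))
            else:
                maps.append(collage_entropy_maps_3d(scene, mask, base))
        for v in v_grid:
            cfg = CollageConfig(
                window_radius=r, orientation_bins=orientation_bins, hist_bins=v
            )
            samples = []
            for (scene, mask, label), ms in zip(cohort, maps):
                if len(ms) == 1:
                    fv = entropy_histogram(ms[0], cfg)
                else:
                    fv = joint_entropy_histogram(ms[0], ms[1], cfg)
                samples.append(Sample(fv.values, label, mask.group_id))
            res = rf_cross_validate(samples, cv_config)
            records.append(
                {
                    "window_radius": r,
                    "window_size": 2 * r + 1,
                    "v": v,
                    "beta_acc_mean": res.beta_acc_mean,
                    "beta_acc_std": res.beta_acc_std,
                }
            )
    return pd.DataFrame(records)
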