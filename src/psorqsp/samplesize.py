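"""Progressive-sampling sample-size estimation.

Learning-curve approach: for increasing subset sizes (starting at 10), a
two-feature linear classifier is trained on repeated stratified subsamples
and scored by k-fold (default 10) cross-validated accuracy.  The minimum
sample size for a threshold (e.g. 90% or 95% of the maximum accuracy, the
accuracy using all samples) is the smallest size whose subsamples meet the
threshold in at least a stated fraction of repeats (the "power").

A cohort-representativity helper converts a comorbidity frequency into the
population size needed for a target cohort (e.g. 15 diabetic patients at a
4.38% frequency require ceil(15 / 0.0438) = 343 subjects).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold, cross_val_score

__all__ = [
    "LearningCurve",
    "progressive_sampling",
    "best_pair_cv_accuracy",
    "min_population_for_cohort",
]

PAIR_SEARCH_CAP = 200  # exhaustive pair search below this many features


def min_population_for_cohort(cohort_size: int, frequency: float) -> int:
    """Smallest population whose expected subgroup at ``frequency`` reaches
    ``cohort_size``: ceil(cohort_size / frequency)."""
    if not 0 < frequency <= 1:
        raise ValueError("frequency must lie in (0, 1]")
    if cohort_size < 1:
        raise ValueError("cohort_size must be >= 1")
    return math.ceil(cohort_size / frequency)


@dataclass(frozen=True)
class LearningCurve:
    sizes: tuple
    mean_accuracy: tuple  # per size, mean over repeats
    sd_accuracy: tuple  # per size, spread over repeats
    repeat_accuracy: tuple  # per size, tuple of per-repeat accuracies
    max_accuracy: float  # accuracy at full n
    thresholds: tuple  # fractions of max accuracy, e.g. (0.90, 0.95)
    min_n: dict  # threshold fraction -> minimum n (None if never reached)
    power: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "size": self.sizes,
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
        })


def best_pair_cv_accuracy(X: np.ndarray, y: np.ndarray, k_folds: int = 10,
                          seed: int = 0) -> float:
    """CV accuracy of the best two-feature linear discriminant.

    Exhaustive search over feature pairs up to ``PAIR_SEARCH_CAP`` features;
    beyond that, greedy: rank features by single-feature CV accuracy and
    search pairs within the top 20.
    """
    n_feat = X.shape[1]
    n_min = min(int((y == 0).sum()), int((y == 1).sum()))
    k = min(k_folds, n_min)
    if k < 2:
        raise ValueError("need at least 2 samples of each class per fold")
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)

    def score(cols) -> float:
        lda = LinearDiscriminantAnalysis()
        return float(np.mean(cross_val_score(lda, X[:, list(cols)], y, cv=cv)))

    if n_feat <= PAIR_SEARCH_CAP:
        pairs = itertools.combinations(range(n_feat), 2)
    else:
        singles = sorted(range(n_feat), key=lambda j: -score((j,)))[:20]
        pairs = itertools.combinations(singles, 2)
    return max(score(p) for p in pairs)


def progressive_sampling(
    features: pd.DataFrame,
    labels,
    sizes=None,
    k_folds: int = 10,
    repeats: int = 20,
    power: float = 0.95,
    thresholds: tuple = (0.90, 0.95),
    seed: int = 0,
    max_retries: int = 50,
) -> LearningCurve:
    """Learning curve of the best two-feature classifier over subset sizes.

    For each size, ``repeats`` stratified subsamples are drawn; each is
    scored by ``best_pair_cv_accuracy``.  ``min_n`` per threshold is the
    smallest size whose repeats meet threshold * max_accuracy in at least
    ``power`` of the repeats.
    """
    X = features.to_numpy(dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("labels must be binary")
    y = (y == classes[1]).astype(int)
    n = len(y)
    if sizes is None:
        sizes = list(range(10, n + 1, max(10, (n - 10) // 10 or 10)))
        if sizes[-1] != n:
            sizes.append(n)
    sizes = sorted(int(s) for s in sizes)
    if sizes[0] < 10:
        raise ValueError("subset sizes start at 10")
    rng = np.random.default_rng(seed)

    max_accuracy = best_pair_cv_accuracy(X, y, k_folds, seed=seed)

    per_size_acc = []
    for size in sizes:
        accs = []
        n_rep = 1 if size >= n else repeats
        for r in range(n_rep):
            if size >= n:
                idx = np.arange(n)
            else:
                for _ in range(max_retries):
                    idx = rng.choice(n, size=size, replace=False)
                    if len(np.unique(y[idx])) == 2 and min(
                        (y[idx] == 0).sum(), (y[idx] == 1).sum()
                    ) >= 2:
                        break
                else:
                    raise RuntimeError(
                        f"could not draw a two-class subsample of size {size}"
                    )
            accs.append(best_pair_cv_accuracy(X[idx], y[idx], k_folds,
                                              seed=seed + r))
        per_size_acc.append(accs)

    min_n = {}
    for frac in thresholds:
        target = frac * max_accuracy
        found = None
        for size, accs in zip(sizes, per_size_acc):
            hit = np.mean([a >= target for a in accs])
            if hit >= power:
                found = size
                break
        min_n[frac] = found

    return LearningCurve(
        sizes=tuple(sizes),
        mean_accuracy=tuple(float(np.mean(a)) for a in per_size_acc),
        sd_accuracy=tuple(float(np.std(a, ddof=1)) if len(a) > 1 else 0.0
                          for a in per_size_acc),
        repeat_accuracy=tuple(tuple(a) for a in per_size_acc),
        max_accuracy=float(max_accuracy),
        thresholds=tuple(thresholds),
        min_n=min_n,
        power=power,
    )
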