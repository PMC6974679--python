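"""Group comparison statistics and cross-validated k-NN classification.

Feature-wise group comparisons follow a normality-gated scheme: a
Kolmogorov–Smirnov (Lilliefors) normality test routes each feature to the
parametric two-sample t-test when both groups look normal and to the
nonparametric Mann–Whitney U test otherwise, with Benjamini–Hochberg FDR
correction across the feature family.

Classification performance of candidate feature sets is assessed by
iterated stratified 10-fold cross-validation of a k-nearest-neighbor
classifier (Euclidean metric, majority vote, ties broken toward the
control class), with optional in-fold rank-based feature selection so no
information leaks from the test subjects into the training pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.diagnostic import kstest_normal
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparisonResult",
    "ClassificationReport",
    "group_compare",
    "rank_select_features",
    "knn_cv",
]


@dataclass
class GroupComparisonResult:
    """Per-feature two-sample test results with FDR adjustment."""

    test: list[str]
    statistic: np.ndarray
    pvalue: np.ndarray
    pvalue_adjusted: np.ndarray
    significant: np.ndarray
    alpha: float


@dataclass
class ClassificationReport:
    """Iterated cross-validation performance in percent."""

    accuracy: np.ndarray  # per iteration
    sensitivity: np.ndarray
    specificity: np.ndarray
    config: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            m: {"mean": float(v.mean()), "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0}
            for m, v in {
                "accuracy": self.accuracy,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }.items()
        }


def _is_normal(x: np.ndarray, alpha: float = 0.05) -> bool:
    if x.std() == 0 or x.size < 4:
        return False
    try:
        _, p = kstest_normal(x)
    except Exception:
        return False
    return p > alpha


def _feature_stat(a: np.ndarray, b: np.ndarray) -> tuple[str, float, float]:
    """Route one feature to t-test or Mann–Whitney; return (name, stat, p)."""
    if a.std() == 0 and b.std() == 0:
        warnings.warn("zero-variance feature; Mann-Whitney route", stacklevel=3)
    if _is_normal(a) and _is_normal(b):
        t, p = sp_stats.ttest_ind(a, b)
        return "t", float(t), float(p)
    try:
        u, p = sp_stats.mannwhitneyu(a, b, alternative="two-sided")
    except ValueError:  # all values identical
        return "mannwhitney", 0.0, 1.0
    # convert U to a signed z statistic for comparable ranking magnitude
    n1, n2 = a.size, b.size
    mu, sigma = n1 * n2 / 2.0, np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    z = (u - mu) / sigma if sigma > 0 else 0.0
    return "mannwhitney", float(z), float(p)


def group_compare(
    features_a: np.ndarray,
    features_b: np.ndarray,
    alpha: float = 0.05,
) -> GroupComparisonResult:
    """Feature-wise group comparison with normality routing and FDR.

    Parameters
    ----------
    features_a, features_b : ndarray (n_subjects, n_features)

    Returns
    -------
    GroupComparisonResult with per-feature test name, statistic, raw and
    BH-adjusted p-values, and significance flags at ``alpha`` on the
    adjusted p-values.
    """
    A = np.atleast_2d(np.asarray(features_a, dtype=float))
    B = np.atleast_2d(np.asarray(features_b, dtype=float))
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("need at least 2 samples per group")
    n_feat = A.shape[1]
    names, stats_, ps = [], np.empty(n_feat), np.empty(n_feat)
    for f in range(n_feat):
        name, s, p = _feature_stat(A[:, f], B[:, f])
        names.append(name)
        stats_[f], ps[f] = s, p
    reject, p_adj, _, _ = multipletests(ps, alpha=alpha, method="fdr_bh")
    return GroupComparisonResult(
        test=names,
        statistic=stats_,
        pvalue=ps,
        pvalue_adjusted=p_adj,
        significant=reject,
        alpha=alpha,
    )


def rank_select_features(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    top_n: int = 10,
) -> np.ndarray:
    """Indices of the ``top_n`` most group-discriminative features.

    Features are ranked by the absolute value of the routed two-sample
    statistic (|t| or |z| from the Mann–Whitney U) computed on the
    training data only; callers must not pass test subjects here.
    """
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels)
    if top_n > X.shape[1]:
        raise ValueError("top_n exceeds the number of features")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("rank selection requires exactly two classes")
    A, B = X[y == classes[0]], X[y == classes[1]]
    scores = np.empty(X.shape[1])
    for f in range(X.shape[1]):
        _, s, _ = _feature_stat(A[:, f], B[:, f])
        scores[f] = abs(s) if np.isfinite(s) else 0.0
    order = np.argsort(-scores, kind="stable")
    return np.sort(order[:top_n])


def _knn_predict(
    X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray, k: int
) -> np.ndarray:
    k_eff = min(k, X_train.shape[0])
    nn = NearestNeighbors(n_neighbors=k_eff).fit(X_train)
    _, idx = nn.kneighbors(X_test)
    votes = (y_train[idx] == 1).sum(axis=1)
    # strict majority required for the patient class; ties -> control (0)
    return (votes > k_eff / 2).astype(int)


def knn_cv(
    features: np.ndarray,
    labels: np.ndarray,
    k: int = 10,
    folds: int = 10,
    iterations: int = 100,
    seed: int = 0,
    select_top_n: int | None = None,
) -> ClassificationReport:
    """Iterated stratified k-fold cross-validation of a k-NN classifier.

    Labels are binary with 1 = patient class (sensitivity) and
    0 = control class (specificity). Per iteration the folds are
    re-drawn (stratified, shuffled under a per-iteration seed), fold
    predictions are pooled into one confusion matrix, and accuracy,
    sensitivity and specificity are recorded in percent; the report keeps
    the per-iteration values for mean ± sd summaries.

    When ``select_top_n`` is given, rank-based feature selection is
    re-run inside every training fold before fitting, so the test fold
    never influences which features are used.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ValueError("each class needs at least `folds` samples")
    min_train = y.size - (y.size // folds + (1 if y.size % folds else 0))
    if min_train < k:
        warnings.warn(
            f"training folds smaller than k={k}; votes use all training points",
            stacklevel=2,
        )

    ss = np.random.SeedSequence(seed)
    iter_seeds = ss.generate_state(iterations)

    acc = np.empty(iterations)
    sens = np.empty(iterations)
    spec = np.empty(iterations)
    for it in range(iterations):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=int(iter_seeds[it] % (2**31))
        )
        y_pred = np.empty_like(y)
        for train_idx, test_idx in skf.split(X, y):
            Xtr, ytr = X[train_idx], y[train_idx]
            Xte = X[test_idx]
            if select_top_n is not None:
                keep = rank_select_features(Xtr, ytr, top_n=select_top_n)
                Xtr, Xte = Xtr[:, keep], Xte[:, keep]
            y_pred[test_idx] = _knn_predict(Xtr, ytr, Xte, k)
        tp = np.sum((y == 1) & (y_pred == 1))
        tn = np.sum((y == 0) & (y_pred == 0))
        acc[it] = 100.0 * (tp + tn) / y.size
        sens[it] = 100.0 * tp / max(counts[1], 1)
        spec[it] = 100.0 * tn / max(counts[0], 1)

    return ClassificationReport(
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        config={
            "k": k,
            "folds": folds,
            "iterations": iterations,
            "seed": seed,
            "select_top_n": select_top_n,
        },
    )
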