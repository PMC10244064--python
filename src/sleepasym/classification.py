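"""Decision-tree classification of epileptic-focus laterality from LI features.

A CART decision tree (Gini impurity, no depth cap, minimum leaf size 1) is
trained on the per-patient lateralization indices inside a stratified 5-fold
cross-validation, the whole procedure repeated with fresh fold assignments
(5000 iterations in the full-scale analysis) to estimate the accuracy and its
standard deviation.  The empirical chance level comes from re-running the
identical procedure with the focus labels randomly permuted at every
iteration.  Significance of the pooled 2x2 contingency table uses Fisher's
exact test, and per-feature importance follows the CART convention: the risk
reduction contributed at each branch node, summed per split feature and
divided by the number of branch nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ClassificationRun",
    "run_repeated_cv",
    "run_shuffle_null",
    "compare_runs",
    "contingency_significance",
    "predictor_importance",
    "low_asymmetry_subset",
]

POSITIVE_CLASS = "left"


@dataclass
class ClassificationRun:
    """Aggregate of a repeated cross-validated classification.

    Per-iteration sensitivity/specificity/PPV/NPV are computed from that
    iteration's pooled held-out predictions with ``left`` focus as the
    positive class; per-iteration accuracy is the fold-weighted mean of fold
    accuracies.  ``contingency`` pools (TP, FP, FN, TN) over all iterations.
    ``importances`` holds the per-iteration raw CART importance per feature
    (iterations x features), before min-max rescaling.
    """

    n_iterations: int
    k_folds: int
    seed: int
    shuffled: bool
    feature_names: list[str]
    accuracy: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    ppv: np.ndarray
    npv: np.ndarray
    contingency: np.ndarray  # 2x2 [[TP, FN], [FP, TN]]
    importances: np.ndarray

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracy.mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.accuracy.std(ddof=1))

    def pooled_metrics(self) -> dict[str, float]:
        """Accuracy/sensitivity/specificity/PPV/NPV from the pooled table."""
        (tp, fn), (fp, tn) = self.contingency
        total = tp + fn + fp + tn

        def _div(a, b):
            return float(a) / float(b) if b else float("nan")

        return {
            "accuracy": _div(tp + tn, total),
            "sensitivity": _div(tp, tp + fn),
            "specificity": _div(tn, tn + fp),
            "ppv": _div(tp, tp + fp),
            "npv": _div(tn, tn + fn),
        }

    def summary(self) -> dict[str, float]:
        return {
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "mean_sensitivity": float(np.nanmean(self.sensitivity)),
            "mean_specificity": float(np.nanmean(self.specificity)),
            "mean_ppv": float(np.nanmean(self.ppv)),
            "mean_npv": float(np.nanmean(self.npv)),
        }


def _validate_matrix(matrix: pd.DataFrame, feature_names: list[str] | None):
    if "label" not in matrix.columns:
        raise ValueError("feature matrix needs a 'label' column")
    labels = matrix["label"].to_numpy()
    classes = set(labels)
    if classes - {"left", "right"}:
        raise ValueError(f"labels must be 'left'/'right', got {sorted(classes)}")
    if len(classes) < 2:
        raise ValueError("degenerate single-class matrix")
    if feature_names is None:
        feature_names = [c for c in matrix.columns if c != "label"]
    X = matrix[feature_names].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    if len(matrix) < 10:
        raise ValueError("at least 10 patients are required for 5-fold CV")
    return X, labels, feature_names


def _tree_importance(tree: DecisionTreeClassifier, n_features: int) -> np.ndarray:
    """CART predictor importance: per-feature risk reduction summed over
    branch nodes, divided by the number of branch nodes."""
    t = tree.tree_
    imp = np.zeros(n_features)
    total_w = t.weighted_n_node_samples[0]
    branch = np.flatnonzero(t.children_left != -1)
    if branch.size == 0:
        return imp
    risk = t.weighted_n_node_samples / total_w * t.impurity
    for node in branch:
        delta = risk[node] - risk[t.children_left[node]] - risk[t.children_right[node]]
        imp[t.feature[node]] += delta
    return imp / branch.size


def run_repeated_cv(
    matrix: pd.DataFrame,
    n_iter: int = 5000,
    k: int = 5,
    seed: int = 0,
    feature_names: list[str] | None = None,
    shuffle_labels: bool = False,
) -> ClassificationRun:
    """Repeated stratified k-fold CV of a CART decision tree.

    Each iteration draws a fresh stratified fold assignment (and, when
    ``shuffle_labels``, a fresh label permutation preserving class counts),
    trains one tree per fold and evaluates it on the held-out fold.  Results
    are deterministic given (matrix, seed).
    """
    X, labels, feature_names = _validate_matrix(matrix, feature_names)
    n = len(labels)
    y_true_base = (labels == POSITIVE_CLASS)
    rng = np.random.default_rng(seed)
    iter_seeds = rng.integers(0, 2**31 - 1, size=n_iter)

    acc = np.empty(n_iter)
    sens = np.empty(n_iter)
    spec = np.empty(n_iter)
    ppv = np.empty(n_iter)
    npv = np.empty(n_iter)
    importances = np.zeros((n_iter, len(feature_names)))
    pooled = np.zeros((2, 2), dtype=np.int64)

    for it in range(n_iter):
        it_rng = np.random.default_rng(iter_seeds[it])
        y = y_true_base
        if shuffle_labels:
            y = y_true_base[it_rng.permutation(n)]
        skf = StratifiedKFold(
            n_splits=k, shuffle=True, random_state=int(it_rng.integers(2**31 - 1))
        )
        fold_acc = []
        tp = fp = fn = tn = 0
        imp = np.zeros(len(feature_names))
        for train, test in skf.split(X, y):
            clf = DecisionTreeClassifier(
                criterion="gini",
                max_depth=None,
                min_samples_leaf=1,
                random_state=int(it_rng.integers(2**31 - 1)),
            )
            clf.fit(X[train], y[train])
            pred = clf.predict(X[test])
            truth = y[test]
            fold_acc.append((pred == truth).mean())
            tp += int(np.sum(pred & truth))
            fp += int(np.sum(pred & ~truth))
            fn += int(np.sum(~pred & truth))
            tn += int(np.sum(~pred & ~truth))
            imp += _tree_importance(clf, len(feature_names))
        acc[it] = np.mean(fold_acc)
        sens[it] = tp / (tp + fn) if tp + fn else np.nan
        spec[it] = tn / (tn + fp) if tn + fp else np.nan
        ppv[it] = tp / (tp + fp) if tp + fp else np.nan
        npv[it] = tn / (tn + fn) if tn + fn else np.nan
        importances[it] = imp / k
        pooled += np.array([[tp, fn], [fp, tn]])

    return ClassificationRun(
        n_iterations=n_iter,
        k_folds=k,
        seed=seed,
        shuffled=shuffle_labels,
        feature_names=feature_names,
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        contingency=pooled,
        importances=importances,
    )


def run_shuffle_null(
    matrix: pd.DataFrame,
    n_iter: int = 5000,
    k: int = 5,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> ClassificationRun:
    """Label-shuffle null: identical procedure with labels permuted anew
    (class counts preserved) at every iteration."""
    return run_repeated_cv(
        matrix, n_iter=n_iter, k=k, seed=seed,
        feature_names=feature_names, shuffle_labels=True,
    )


def compare_runs(*runs: ClassificationRun, names: list[str] | None = None) -> pd.DataFrame:
    """Compare per-iteration accuracies across runs.

    Two runs: unpaired t-test.  Three or more: one-way ANOVA followed by all
    pairwise unpaired t-tests with Sidak adjustment.  Identical accuracy
    vectors get the degenerate p = 1 marker.
    """
    if len(runs) < 2:
        raise ValueError("need at least two runs to compare")
    n_iter = {r.n_iterations for r in runs}
    if len(n_iter) != 1:
        raise ValueError("runs must share the same number of iterations")
    if names is None:
        names = [f"run{i}" for i in range(len(runs))]
    accs = [r.accuracy for r in runs]

    if len(runs) > 2:
        anova_f, anova_p = sst.f_oneway(*accs)
    else:
        anova_f = anova_p = np.nan

    pairs = list(zip(*np.triu_indices(len(runs), k=1)))
    m = len(pairs)
    rows = []
    for i, j in pairs:
        if np.array_equal(accs[i], accs[j]):
            t, p = 0.0, 1.0
        else:
            t, p = sst.ttest_ind(accs[i], accs[j])
        p_adj = min(1.0, 1.0 - (1.0 - float(p)) ** m) if m > 1 else float(p)
        rows.append(
            {
                "run_a": names[i],
                "run_b": names[j],
                "mean_diff": float(accs[i].mean() - accs[j].mean()),
                "t": float(t),
                "p_raw": float(p),
                "p_adj": p_adj,
                "anova_f": float(anova_f) if m > 1 else np.nan,
                "anova_p": float(anova_p) if m > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def contingency_significance(run: ClassificationRun) -> float:
    """Two-sided Fisher's exact p on the run's pooled 2x2 table.

    A table with a zero margin carries no association information: p = 1.
    """
    table = np.asarray(run.contingency, dtype=np.int64)
    if table.sum() <= 0:
        raise ValueError("contingency table is empty")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0
    return float(sst.fisher_exact(table, alternative="two-sided")[1])


def predictor_importance(run: ClassificationRun) -> pd.Series:
    """Per-feature importance averaged over all iterations, min-max rescaled
    so 0 is the smallest importance and 1 the highest."""
    mean_imp = run.importances.mean(axis=0)
    span = mean_imp.max() - mean_imp.min()
    scaled = (mean_imp - mean_imp.min()) / span if span > 0 else np.zeros_like(mean_imp)
    return pd.Series(scaled, index=run.feature_names, name="importance")


def low_asymmetry_subset(
    matrix: pd.DataFrame,
    ied_feature: str = "ied_rate",
    n_iter: int = 500,
    k: int = 5,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> dict:
    """Re-classify the difficult-to-lateralize patients.

    Selects patients whose |LI(IED)| is strictly below the cohort median
    |LI(IED)|, re-runs the repeated CV on that subset and compares the
    per-iteration feature importances with Kruskal-Wallis + Dunn across
    iterations.  Fewer than 6 selected patients flags the result; an empty
    subset (all |LI| tied at the median) returns the empty-subset marker.
    """
    from .asymmetry_stats import dunn_test

    if ied_feature not in matrix.columns:
        raise ValueError(f"matrix lacks the {ied_feature!r} feature")
    abs_li = matrix[ied_feature].abs()
    cutoff = abs_li.median()
    subset = matrix[abs_li < cutoff]
    report: dict = {
        "cutoff": float(cutoff),
        "n_subset": int(len(subset)),
        "patients": list(subset.index),
        "flagged": len(subset) < 6,
    }
    if len(subset) == 0:
        report["empty_subset"] = True
        return report
    report["empty_subset"] = False
    if len(subset) < 10 or subset["label"].nunique() < 2:
        # too small for a meaningful 5-fold CV; report the selection only
        report["flagged"] = True
        return report
    run = run_repeated_cv(
        subset, n_iter=n_iter, k=k, seed=seed, feature_names=feature_names
    )
    report["run"] = run
    report["importance"] = predictor_importance(run)
    samples = {
        name: run.importances[:, i] for i, name in enumerate(run.feature_names)
    }
    comparisons = [
        (a, b)
        for idx, a in enumerate(run.feature_names)
        for b in run.feature_names[idx + 1:]
    ]
    _, kw_p = sst.kruskal(*samples.values())
    report["kruskal_p"] = float(kw_p)
    report["dunn"] = dunn_test(samples, comparisons)
    return report
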