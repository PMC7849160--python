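"""Cross-validated classifier comparison and permutation (mean-decrease-accuracy) importance.

Continuous per-sample stability scores are discretized into quantile classes
(default 3 bins), seven standard classifier families are compared under
identical repeated stratified k-fold splits, and functional-category
importance is the mean decrease in held-out random-forest accuracy when one
category's values are permuted. The learners are stock scikit-learn
estimators; the contribution here is the harness (shared folds, repeats,
error aggregation, seeded permutation importance). A regression mode scores
the permutation drop in R^2 instead, for users who prefer not to bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import (
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.metrics import accuracy_score, r2_score
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "discretize_target",
    "default_methods",
    "compare_methods",
    "mean_decrease_accuracy",
    "CvReport",
    "ImportanceReport",
]


def discretize_target(values, n_bins: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Quantile-bin a continuous target into near-equal-count classes.

    Returns (integer labels, bin edges). Heavy ties that collapse a bin are an
    error with guidance, not a silent class merge.
    """
    vals = np.asarray(values, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if np.unique(vals).size < n_bins:
        raise ValueError(
            f"only {np.unique(vals).size} distinct values for {n_bins} bins; "
            "reduce n_bins or use the regression mode"
        )
    labels, edges = pd.qcut(vals, q=n_bins, labels=False, retbins=True, duplicates="drop")
    if np.unique(labels).size < n_bins:
        raise ValueError(
            "ties collapsed a quantile bin; reduce n_bins or jitter/use regression mode"
        )
    return np.asarray(labels, dtype=int), edges


def default_methods(seed: int = 0) -> dict[str, object]:
    """The seven compared classifier families, seeded where stochastic."""
    return {
        "decision_tree": DecisionTreeClassifier(random_state=seed),
        "boosting": GradientBoostingClassifier(random_state=seed),
        "bagging": BaggingClassifier(random_state=seed),
        "nearest_neighbor": KNeighborsClassifier(),
        "support_vector_machine": make_pipeline(StandardScaler(), SVC(random_state=seed)),
        "random_forest": RandomForestClassifier(random_state=seed, n_estimators=300),
        "neural_network": make_pipeline(
            StandardScaler(),
            MLPClassifier(random_state=seed, max_iter=2000, hidden_layer_sizes=(32,)),
        ),
    }


@dataclass
class CvReport:
    method: str
    fold_errors: np.ndarray  # folds x repeats flattened
    mean_error: float
    sd_error: float

    def as_row(self) -> dict:
        return {"method": self.method, "mean_error": self.mean_error,
                "sd_error": self.sd_error, "n_fold_evaluations": self.fold_errors.size}


def compare_methods(
    X,
    y,
    methods: dict[str, object] | None = None,
    folds: int = 10,
    repeats: int = 1,
    seed: int = 0,
) -> dict[str, CvReport]:
    """Repeated stratified k-fold error per method on identical fold assignments.

    Every method sees the same splits (same seed), so differences reflect the
    learners, not the folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples; cannot stratify {folds} folds"
        )
    if methods is None:
        methods = default_methods(seed)
    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    splits = list(cv.split(X, y))
    reports = {}
    for name, est in methods.items():
        errs = []
        for train, test in splits:
            model = clone(est)
            model.fit(X[train], y[train])
            errs.append(1.0 - accuracy_score(y[test], model.predict(X[test])))
        errs = np.array(errs)
        reports[name] = CvReport(name, errs, float(errs.mean()), float(errs.std(ddof=1)))
    return reports


@dataclass
class ImportanceReport:
    importances: pd.Series  # mean decrease accuracy per feature
    ranks: pd.Series  # 1 = most important
    repeats: int
    seed: int
    baseline_score: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean_decrease_accuracy": self.importances,
                             "rank": self.ranks}).sort_values("rank")


def mean_decrease_accuracy(
    X,
    y,
    feature_names=None,
    repeats: int = 10,
    seed: int = 0,
    folds: int = 5,
    mode: str = "classification",
) -> ImportanceReport:
    """Permutation importance of each feature for a random forest.

    For each cross-validation fold the forest is fit on the training part;
    importance of feature j is the drop in held-out accuracy (classification)
    or R^2 (regression) when column j of the held-out block is permuted,
    averaged over ``repeats`` permutations and all folds. Deterministic for a
    fixed seed; ranks follow features, not column positions.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"feature_{j}" for j in range(p)]
    rng = np.random.default_rng(seed)
    if mode == "classification":
        if np.unique(y).size < 2:
            raise ValueError("single-class target; importance undefined")
        est = RandomForestClassifier(random_state=seed, n_estimators=300)
        score = accuracy_score
        from sklearn.model_selection import StratifiedKFold

        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(X, y)
    elif mode == "regression":
        est = RandomForestRegressor(random_state=seed, n_estimators=300)
        score = r2_score
        from sklearn.model_selection import KFold

        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(X)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    drops = np.zeros(p)
    baselines = []
    n_folds = 0
    for train, test in split_iter:
        model = clone(est)
        model.fit(X[train], y[train])
        base = score(y[test], model.predict(X[test]))
        baselines.append(base)
        n_folds += 1
        for j in range(p):
            acc = 0.0
            for _ in range(repeats):
                Xp = X[test].copy()
                Xp[:, j] = Xp[rng.permutation(len(test)), j]
                acc += score(y[test], model.predict(Xp))
            drops[j] += base - acc / repeats
    drops /= n_folds
    imp = pd.Series(drops, index=list(feature_names), name="mean_decrease_accuracy")
    order = imp.sort_values(ascending=False, kind="mergesort")
    ranks = pd.Series(np.arange(1, p + 1), index=order.index).reindex(imp.index)
    return ImportanceReport(
        importances=imp, ranks=ranks, repeats=repeats, seed=seed,
        baseline_score=float(np.mean(baselines)),
    )
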