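"""Random-forest diagnostics with repeated stratified cross-validation.

AUC is computed by the rank statistic (ties get half credit), feature
ranking by mean decrease in impurity averaged over training folds, and
the feature-count curve re-ranks features inside every training fold so
no test-fold information leaks into selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import RepeatedStratifiedKFold

logger = logging.getLogger(__name__)


@dataclass
class CVSpec:
    n_folds: int = 5
    n_repeats: int = 5
    stratified: bool = True
    seed: int = 0
    n_trees: int = 500
    importance: str = "impurity"  # or "permutation"

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.importance not in ("impurity", "permutation"):
            raise ValueError("importance must be 'impurity' or 'permutation'")


@dataclass
class ClassifierReport:
    auc_per_fold: np.ndarray  # n_repeats x n_folds
    mean_auc: float
    importance_ranking: pd.Series  # feature -> mean importance, descending
    feature_curve: list[tuple[int, float]] = field(default_factory=list)


def rank_auc(y_true, scores) -> float:
    """AUC via the Mann-Whitney rank statistic; tied scores get 0.5 credit."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n1 = int(y_true.sum())
    n0 = y_true.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes")
    ranks = stats.rankdata(scores)
    u = ranks[y_true == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _check_xy(X: pd.DataFrame, y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    if len(X) != y.size:
        raise ValueError("X and y length mismatch")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.tolist()}")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    return y


def _fit_forest(X: np.ndarray, y: np.ndarray, spec: CVSpec, seed: int) -> RandomForestClassifier:
    clf = RandomForestClassifier(n_estimators=spec.n_trees, random_state=seed, n_jobs=1)
    clf.fit(X, y)
    return clf


def _importance(clf, X, y, spec: CVSpec, seed: int) -> np.ndarray:
    if spec.importance == "impurity":
        return clf.feature_importances_
    res = permutation_importance(clf, X, y, n_repeats=5, random_state=seed, n_jobs=1)
    return res.importances_mean


def cross_validated_auc(X: pd.DataFrame, y, spec: CVSpec | None = None) -> ClassifierReport:
    """Out-of-fold AUC per fold, mean AUC, and cross-fold importance ranking."""
    spec = spec or CVSpec()
    y = _check_xy(X, y)
    cv = RepeatedStratifiedKFold(
        n_splits=spec.n_folds, n_repeats=spec.n_repeats, random_state=spec.seed
    )
    Xv = X.to_numpy(dtype=float)
    aucs = np.zeros(spec.n_repeats * spec.n_folds)
    imp = np.zeros(X.shape[1])
    for k, (tr, te) in enumerate(cv.split(Xv, y)):
        clf = _fit_forest(Xv[tr], y[tr], spec, seed=spec.seed + 1000 + k)
        proba = clf.predict_proba(Xv[te])[:, list(clf.classes_).index(1)]
        aucs[k] = rank_auc(y[te], proba)
        imp += _importance(clf, Xv[tr], y[tr], spec, seed=spec.seed + 2000 + k)
    imp /= spec.n_repeats * spec.n_folds
    ranking = pd.Series(imp, index=X.columns).sort_values(ascending=False, kind="mergesort")
    return ClassifierReport(
        auc_per_fold=aucs.reshape(spec.n_repeats, spec.n_folds),
        mean_auc=float(aucs.mean()),
        importance_ranking=ranking,
    )


def feature_count_curve(
    X: pd.DataFrame, y, spec: CVSpec | None = None, ks: list[int] | None = None
) -> list[tuple[int, float]]:
    """Mean CV AUC as a function of the number of top-ranked features.

    Features are ranked on each training fold only and the top-k model is
    evaluated on the matching test fold, so selection never sees test
    data.
    """
    spec = spec or CVSpec()
    y = _check_xy(X, y)
    if ks is None:
        ks = sorted({1, 2, 5, 10, X.shape[1]})
    if any(k > X.shape[1] for k in ks):
        logger.warning("k values above the feature count were clamped")
    ks = sorted({min(k, X.shape[1]) for k in ks})
    cv = RepeatedStratifiedKFold(
        n_splits=spec.n_folds, n_repeats=spec.n_repeats, random_state=spec.seed
    )
    Xv = X.to_numpy(dtype=float)
    sums = {k: 0.0 for k in ks}
    n_folds_total = 0
    for f, (tr, te) in enumerate(cv.split(Xv, y)):
        clf = _fit_forest(Xv[tr], y[tr], spec, seed=spec.seed + 1000 + f)
        order = np.argsort(-_importance(clf, Xv[tr], y[tr], spec, seed=spec.seed + 2000 + f),
                           kind="mergesort")
        for k in ks:
            cols = order[:k]
            sub = _fit_forest(Xv[tr][:, cols], y[tr], spec, seed=spec.seed + 3000 + f)
            proba = sub.predict_proba(Xv[te][:, cols])[:, list(sub.classes_).index(1)]
            sums[k] += rank_auc(y[te], proba)
        n_folds_total += 1
    return [(k, sums[k] / n_folds_total) for k in ks]


def combined_model(
    X_virus: pd.DataFrame,
    X_bacteria: pd.DataFrame,
    y,
    spec: CVSpec | None = None,
) -> dict[str, ClassifierReport]:
    """Virus-only, bacteria-only and combined reports on aligned samples.

    Combined features are prefixed ``virus:`` / ``bacteria:`` so class
    dominance among top-ranked predictors can be tabulated.  An empty
    bacterial table degrades to the virus-only model.
    """
    spec = spec or CVSpec()
    if X_bacteria.shape[1] and not X_virus.index.equals(X_bacteria.index):
        offenders = sorted(set(X_virus.index).symmetric_difference(X_bacteria.index))
        raise ValueError(f"sample ids do not align: {offenders[:5]}")
    xv = X_virus.add_prefix("virus:")
    xb = X_bacteria.add_prefix("bacteria:")
    combined = pd.concat([xv, xb], axis=1) if xb.shape[1] else xv
    out = {"virus": cross_validated_auc(xv, y, spec)}
    out["bacteria"] = cross_validated_auc(xb, y, spec) if xb.shape[1] else out["virus"]
    out["combined"] = cross_validated_auc(combined, y, spec) if xb.shape[1] else out["virus"]
    return out


def importance_class_counts(report: ClassifierReport, top_k: int = 10) -> dict[str, int]:
    """How many of the top-k ranked features come from each feature class."""
    counts: dict[str, int] = {}
    for name in report.importance_ranking.index[:top_k]:
        cls = name.split(":", 1)[0] if ":" in name else "unknown"
        counts[cls] = counts.get(cls, 0) + 1
    return counts
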