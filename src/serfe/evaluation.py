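"""Stratified cross-validated classification of the refined feature panel.

Three classifier families — a linear-kernel support vector machine, a random
forest, and k-nearest neighbours — are each evaluated with stratified k-fold
cross-validation.  Per-feature standardization is fit on the training folds
only, so no test-fold statistics leak into the model.  Metrics (balanced
accuracy, precision, recall, F1) are reported as percentages per fold and
aggregated as mean +/- sd; ROC curves and AUC are computed from the pooled
out-of-fold scores.

AUC uses the rank (Mann-Whitney) formulation: the probability that a random
positive outranks a random negative, with ties counted one half.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import FeatureMatrix, PipelineConfig
from .errors import ValidationError
from .weighting import RefinedFeatureSet

CLASSIFIERS = ("svm", "random_forest", "knn")
METRICS = ("balanced_accuracy", "precision", "recall", "f1")


@dataclass
class EvalReport:
    """Fold-wise and aggregate classification metrics per classifier family."""

    per_fold: dict[str, list[dict[str, float]]]
    summary: dict[str, dict[str, dict[str, float]]]  # clf -> metric -> {mean, sd}
    auc: dict[str, float]
    roc_points: dict[str, pd.DataFrame]
    fold_assignment: np.ndarray
    seed: int

    def to_dict(self) -> dict:
        return {
            "per_fold": self.per_fold,
            "summary": self.summary,
            "auc": self.auc,
            "fold_assignment": self.fold_assignment.tolist(),
            "seed": self.seed,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def stratified_folds(labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment (values 0..k-1, one per patient)."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValidationError("stratified folds need both classes present")
    if k > counts.min():
        raise ValidationError(
            f"cannot make {k} stratified folds with a minority class of {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(labels.shape[0], dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros_like(labels), labels)):
        assignment[test_idx] = fold
    return assignment


def classification_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """Confusion-matrix metrics in percent, with degenerate cells -> 0."""
    if min(tp, fp, tn, fn) < 0 or tp + fp + tn + fn == 0:
        raise ValidationError("confusion counts must be nonnegative with total > 0")
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    ba = (recall + specificity) / 2
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    return {
        "balanced_accuracy": 100 * ba,
        "precision": 100 * precision,
        "recall": 100 * recall,
        "specificity": 100 * specificity,
        "f1": 100 * f1,
    }


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[float, pd.DataFrame]:
    """Rank-based AUC (ties count one half) and the threshold-swept ROC curve."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC undefined with a single class")
    ranks = rankdata(scores)  # average ranks handle ties with weight 1/2
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, thresh = roc_curve(labels, scores)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresh})
    return float(auc), curve


def _make_classifiers(seed: int) -> dict[str, object]:
    return {
        "svm": SVC(kernel="linear", C=1.0, random_state=seed),
        "random_forest": RandomForestClassifier(n_estimators=200, random_state=seed),
        "knn": KNeighborsClassifier(n_neighbors=5),
    }


def _scores(clf, name: str, X: np.ndarray) -> np.ndarray:
    if name == "svm":
        return clf.decision_function(X)
    return clf.predict_proba(X)[:, 1]


def evaluate(
    refined: RefinedFeatureSet | FeatureMatrix,
    labels: np.ndarray | None = None,
    config: PipelineConfig | None = None,
) -> EvalReport:
    """Cross-validated evaluation of the refined panel with three classifiers."""
    config = config or PipelineConfig()
    matrix = refined.matrix if isinstance(refined, RefinedFeatureSet) else refined
    if labels is None:
        labels = matrix.labels
    if labels is None:
        raise ValidationError("evaluation needs binary labels")
    labels = np.asarray(labels).astype(int)
    if labels.shape[0] != matrix.n_patients:
        raise ValidationError("need one label per patient")
    X, y = matrix.values, labels
    assignment = stratified_folds(y, config.cv_folds, config.seed)

    per_fold: dict[str, list[dict[str, float]]] = {c: [] for c in CLASSIFIERS}
    pooled_scores: dict[str, np.ndarray] = {
        c: np.empty(len(y), dtype=float) for c in CLASSIFIERS
    }
    for fold in range(config.cv_folds):
        test = assignment == fold
        train = ~test
        if len(np.unique(y[test])) < 2 or len(np.unique(y[train])) < 2:
            raise ValidationError(f"fold {fold} is single-class; cohort too small")
        scaler = StandardScaler().fit(X[train])
        Xtr, Xte = scaler.transform(X[train]), scaler.transform(X[test])
        for name, clf in _make_classifiers(config.seed).items():
            clf.fit(Xtr, y[train])
            pred = clf.predict(Xte)
            tp = int(((pred == 1) & (y[test] == 1)).sum())
            fp = int(((pred == 1) & (y[test] == 0)).sum())
            tn = int(((pred == 0) & (y[test] == 0)).sum())
            fn = int(((pred == 0) & (y[test] == 1)).sum())
            per_fold[name].append(classification_metrics(tp, fp, tn, fn))
            pooled_scores[name][test] = _scores(clf, name, Xte)

    summary: dict[str, dict[str, dict[str, float]]] = {}
    auc: dict[str, float] = {}
    roc_points: dict[str, pd.DataFrame] = {}
    for name in CLASSIFIERS:
        summary[name] = {}
        for metric in per_fold[name][0]:
            vals = np.array([f[metric] for f in per_fold[name]])
            summary[name][metric] = {
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)),
            }
        auc_val, curve = roc_auc(pooled_scores[name], y)
        auc[name] = auc_val
        roc_points[name] = curve
    return EvalReport(
        per_fold=per_fold,
        summary=summary,
        auc=auc,
        roc_points=roc_points,
        fold_assignment=assignment,
        seed=config.seed,
    )
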