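"""Supervised evaluation of descriptor vectors.

Stratified 10-fold cross-validation of random forests (50 trees) and
RBF-kernel SVMs over superindex feature vectors, confusion-matrix
performance metrics (accuracy, sensitivity, specificity, precision,
F-measure — the harmonic mean of precision and sensitivity), CFS-style
greedy forward feature selection, and the random-subset experiment
comparing unlabeled-only with mixed unlabeled+labeled feature sets.
The positive class is label 1 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .descriptors import DescriptorTable


@dataclass
class ClassificationReport:
    """Pooled-confusion metrics (percent) of a cross-validated model."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float | None
    f_measure: float | None
    confusion: tuple[int, int, int, int]  # tp, fp, tn, fn
    per_fold: dict[str, list[float]] = field(default_factory=dict)
    model_config: str = ""


def f_measure(precision: float, sensitivity: float) -> float:
    """Harmonic mean of precision and sensitivity (same scale in and out)."""
    if precision + sensitivity == 0:
        return 0.0
    return 2.0 * precision * sensitivity / (precision + sensitivity)


def accuracy_from_rates(
    sensitivity: float, specificity: float, n_pos: int, n_neg: int
) -> float:
    """Accuracy implied by class-conditional rates and the class counts."""
    return (sensitivity * n_pos + specificity * n_neg) / (n_pos + n_neg)


def metrics_from_confusion(tp: int, fp: int, tn: int, fn: int) -> ClassificationReport:
    """Performance metrics, in percent, from confusion counts."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both classes must be present")
    total = tp + fp + tn + fn
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp)
    acc = 100.0 * (tp + tn) / total
    prec = 100.0 * tp / (tp + fp) if tp + fp > 0 else None
    f = f_measure(prec, sens) if prec is not None else None
    return ClassificationReport(
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        f_measure=f,
        confusion=(tp, fp, tn, fn),
    )


def _make_model(model: str, n_features: int, seed: int, optimize: bool):
    if model == "rf":
        clf = RandomForestClassifier(n_estimators=50, random_state=seed)
        pipe = Pipeline([("scale", StandardScaler()), ("clf", clf)])
        return pipe, "rf(50 trees)"
    if model == "svm":
        pipe = Pipeline([("scale", StandardScaler()), ("clf", SVC(kernel="rbf"))])
        if optimize:
            grid = {
                "clf__C": [0.1, 1.0, 10.0, 100.0],
                "clf__gamma": [0.1 / n_features, 1.0 / n_features, 10.0 / n_features],
            }
            return (
                GridSearchCV(pipe, grid, cv=5, scoring="accuracy", n_jobs=1),
                "svm(rbf, grid-searched)",
            )
        return pipe, "svm(rbf)"
    raise ValueError(f"unknown model {model!r}")


def crossvalidate(
    table: DescriptorTable,
    model: str = "rf",
    folds: int = 10,
    seed: int = 0,
    optimize: bool = False,
    features: list[str] | None = None,
) -> ClassificationReport:
    """Stratified k-fold cross-validation over a labeled descriptor table.

    Features are standardised inside each training fold; metrics are
    computed from the confusion matrix pooled over folds, with per-fold
    metric vectors retained in ``per_fold``.  Fully deterministic given
    (table, model, seed).
    """
    X = table.X(features)
    y = table.y
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need both classes present")
    if counts.min() < folds:
        raise ValueError("need at least `folds` rows per class")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    tp = fp = tn = fn = 0
    per_fold: dict[str, list[float]] = {k: [] for k in ("accuracy", "sensitivity", "specificity", "precision", "f_measure")}
    cfg = ""
    for train, test in skf.split(X, y):
        est, cfg = _make_model(model, X.shape[1], seed, optimize)
        est.fit(X[train], y[train])
        pred = est.predict(X[test])
        t = y[test]
        ftp = int(np.sum((pred == 1) & (t == 1)))
        ffp = int(np.sum((pred == 1) & (t == 0)))
        ftn = int(np.sum((pred == 0) & (t == 0)))
        ffn = int(np.sum((pred == 0) & (t == 1)))
        tp, fp, tn, fn = tp + ftp, fp + ffp, tn + ftn, fn + ffn
        try:
            r = metrics_from_confusion(ftp, ffp, ftn, ffn)
            for k in per_fold:
                val = getattr(r, k)
                per_fold[k].append(np.nan if val is None else val)
        except ValueError:  # degenerate fold
            for k in per_fold:
                per_fold[k].append(np.nan)
    report = metrics_from_confusion(tp, fp, tn, fn)
    report.per_fold = per_fold
    report.model_config = f"{cfg}, {folds}-fold, seed={seed}"
    return report


def greedy_feature_selection(
    table: DescriptorTable,
    target_size: int | None = None,
    seed: int = 0,
) -> list[str]:
    """CFS-style greedy forward selection of descriptor columns.

    The subset merit rewards features correlated with the class and
    penalises features correlated with each other:
    ``merit = k r_cf / sqrt(k + k (k-1) r_ff)`` with mean absolute Pearson
    correlations.  Selection stops when the merit stops improving, or
    continues to *target_size* when one is requested.
    """
    names = table.feature_names
    if len(names) < 1:
        raise ValueError("no features")
    X = table.X()
    y = table.y.astype(float)

    def corr(a: np.ndarray, b: np.ndarray) -> float:
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            return 0.0
        return float(abs(np.corrcoef(a, b)[0, 1]))

    r_cf = np.array([corr(X[:, i], y) for i in range(len(names))])
    r_ff = np.eye(len(names))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r_ff[i, j] = r_ff[j, i] = corr(X[:, i], X[:, j])

    def merit(idx: list[int]) -> float:
        k = len(idx)
        rcf = r_cf[idx].mean()
        rff = 0.0
        if k > 1:
            pairs = [(a, b) for ii, a in enumerate(idx) for b in idx[ii + 1:]]
            rff = float(np.mean([r_ff[a, b] for a, b in pairs]))
        return k * rcf / np.sqrt(k + k * (k - 1) * rff)

    selected: list[int] = []
    remaining = list(range(len(names)))
    best_merit = -np.inf
    limit = target_size if target_size is not None else len(names)
    while remaining and len(selected) < limit:
        scored = sorted(
            ((merit(selected + [i]), i) for i in remaining), key=lambda t: (-t[0], t[1])
        )
        m, i = scored[0]
        if target_size is None and m <= best_merit:
            break
        best_merit = max(best_merit, m)
        selected.append(i)
        remaining.remove(i)
    return [names[i] for i in selected]


def subset_experiment(
    table: DescriptorTable,
    model: str = "rf",
    n_subsets: int = 10,
    folds: int = 10,
    seed: int = 0,
    optimize: bool = False,
) -> dict[str, dict[str, object]]:
    """Random-subset comparison of unlabeled-only vs mixed feature sets.

    Draws *n_subsets* random subsets of 7 unlabeled descriptors, and
    *n_subsets* subsets of 5 unlabeled + 2 labeled descriptors, runs
    k-fold CV on each, and reports mean and standard deviation per metric
    for both regimes.
    """
    rng = np.random.default_rng(seed)
    unlab = table.features_in_group("unlabeled")
    lab = table.features_in_group("labeled")
    if len(unlab) < 7 or len(lab) < 2:
        raise ValueError("need >= 7 unlabeled and >= 2 labeled features")

    def run(regime: str) -> dict[str, object]:
        reports = []
        subsets = []
        for _ in range(n_subsets):
            if regime == "unlabeled_only":
                feats = sorted(rng.choice(unlab, size=7, replace=False))
            else:
                feats = sorted(rng.choice(unlab, size=5, replace=False)) + sorted(
                    rng.choice(lab, size=2, replace=False)
                )
            subsets.append(feats)
            reports.append(
                crossvalidate(
                    table, model=model, folds=folds, seed=seed,
                    optimize=optimize, features=feats,
                )
            )
        summary: dict[str, object] = {"subsets": subsets, "reports": reports}
        for metric in ("accuracy", "sensitivity", "specificity", "precision", "f_measure"):
            vals = np.array([getattr(r, metric) for r in reports], dtype=float)
            summary[metric] = (float(vals.mean()), float(vals.std(ddof=0)))
        return summary

    return {"unlabeled_only": run("unlabeled_only"), "mixed": run("mixed")}
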