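"""Multi-classifier evaluation harness.

Seven classifier presets — linear/quadratic/cubic SVM, cosine KNN,
weighted KNN, random-subspace KNN and random-subspace discriminant —
scored with stratified ten-fold cross-validation (or an 80:20 holdout)
on a deep-feature table. The preset names and hyperparameters mirror
the MATLAB Classification Learner presets these classifier families are
commonly reported with; the registry freezes the exact values for
reproducibility:

* linear/quadratic/cubic SVM: polynomial kernel of degree 1/2/3, box
  constraint C=1, one-vs-one decision;
* cosine KNN: k=10, cosine distance;
* weighted KNN: k=10, squared-inverse distance weights, Euclidean;
* subspace KNN: random-subspace ensemble of 30 one-nearest-neighbor
  learners, each on ceil(d/2) features;
* subspace discriminant: same ensemble with linear-discriminant base
  learners ("subspace decrement" is accepted as an alias, a typo seen
  in the wild for subspace discriminant).

Every preset is scored on the identical seeded fold partition; features
are standardized per fold with training-fold statistics only; metrics
(accuracy, macro precision/recall as percentages, macro one-vs-rest AUC,
wall time) aggregate over the pooled out-of-fold predictions.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import BaggingClassifier
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureTable

__all__ = [
    "ClassifierPreset",
    "EvalReport",
    "PRESET_NAMES",
    "make_preset",
    "build_estimator",
    "crossval_evaluate",
    "holdout_evaluate",
    "write_report",
]

PRESET_NAMES = (
    "linear_svm",
    "quadratic_svm",
    "cubic_svm",
    "cosine_knn",
    "weighted_knn",
    "subspace_knn",
    "subspace_discriminant",
)

_ALIASES = {
    "subspace decrement": "subspace_discriminant",
    "subspace_decrement": "subspace_discriminant",
    "subspace discriminant": "subspace_discriminant",
}


@dataclass(frozen=True)
class ClassifierPreset:
    name: str
    hyperparameters: dict = field(default_factory=dict)


def _squared_inverse(dist: np.ndarray) -> np.ndarray:
    return 1.0 / (dist**2 + 1e-12)


def make_preset(name: str) -> ClassifierPreset:
    """Look up a preset by name (aliases resolved, case-insensitive)."""
    key = name.strip().lower()
    key = _ALIASES.get(key, key)
    if key not in PRESET_NAMES:
        raise ValueError(
            f"unknown classifier preset {name!r}; registry: {', '.join(PRESET_NAMES)}"
        )
    hp: dict
    if key in ("linear_svm", "quadratic_svm", "cubic_svm"):
        degree = {"linear_svm": 1, "quadratic_svm": 2, "cubic_svm": 3}[key]
        hp = {"kernel": "poly", "degree": degree, "C": 1.0, "coef0": 1.0,
              "gamma": "scale", "multiclass": "one-vs-one"}
    elif key == "cosine_knn":
        hp = {"n_neighbors": 10, "metric": "cosine"}
    elif key == "weighted_knn":
        hp = {"n_neighbors": 10, "metric": "euclidean", "weights": "squared_inverse"}
    else:
        base = "1nn" if key == "subspace_knn" else "linear_discriminant"
        hp = {"n_estimators": 30, "base": base, "subspace_dim": "ceil(d/2)"}
    return ClassifierPreset(key, hp)


def build_estimator(preset: ClassifierPreset, n_features: int, seed: int):
    """Instantiate the scikit-learn estimator realizing a preset."""
    name = preset.name
    if name in ("linear_svm", "quadratic_svm", "cubic_svm"):
        return SVC(
            kernel="poly",
            degree=preset.hyperparameters["degree"],
            C=1.0,
            coef0=1.0,
            gamma="scale",
            decision_function_shape="ovr",
            random_state=seed,
        )
    if name == "cosine_knn":
        return KNeighborsClassifier(n_neighbors=10, metric="cosine")
    if name == "weighted_knn":
        return KNeighborsClassifier(
            n_neighbors=10, metric="euclidean", weights=_squared_inverse
        )
    subspace = max(1, int(np.ceil(n_features / 2)))
    if name == "subspace_knn":
        base = KNeighborsClassifier(n_neighbors=1)
    else:
        base = LinearDiscriminantAnalysis()
    return BaggingClassifier(
        estimator=base,
        n_estimators=30,
        max_features=subspace,
        max_samples=1.0,
        bootstrap=False,
        bootstrap_features=False,
        random_state=seed,
    )


@dataclass
class EvalReport:
    rows: list[dict]
    confusion: dict[str, np.ndarray]
    cv_folds: int
    seed: int
    mode: str
    partition_hash: str
    class_names: list[str] | None = None


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _scores(est, X: np.ndarray, n_classes: int) -> np.ndarray:
    """(N, C) probability-like scores for macro one-vs-rest AUC."""
    if hasattr(est, "predict_proba"):
        p = est.predict_proba(X)
    else:
        d = est.decision_function(X)
        if d.ndim == 1:
            d = np.column_stack([-d, d])
        p = _softmax(d)
    if p.shape[1] != n_classes:  # a fold may have seen fewer classes
        full = np.full((len(X), n_classes), 1e-9)
        for j, c in enumerate(est.classes_):
            full[:, int(c)] = p[:, j]
        p = full / full.sum(axis=1, keepdims=True)
    return p


def _macro_auc(y: np.ndarray, scores: np.ndarray) -> float:
    if len(np.unique(y)) < 2:
        return float("nan")
    if scores.shape[1] == 2:
        return float(roc_auc_score(y, scores[:, 1]))
    return float(
        roc_auc_score(y, scores, multi_class="ovr", average="macro",
                      labels=np.arange(scores.shape[1]))
    )


def _metrics_row(name: str, y: np.ndarray, pred: np.ndarray,
                 scores: np.ndarray, elapsed: float) -> dict:
    return {
        "classifier": name,
        "accuracy": 100.0 * accuracy_score(y, pred),
        "time_s": elapsed,
        "auc": _macro_auc(y, scores),
        "precision": 100.0 * precision_score(y, pred, average="macro",
                                             zero_division=0),
        "recall": 100.0 * recall_score(y, pred, average="macro", zero_division=0),
    }


def crossval_evaluate(table: FeatureTable, presets, folds: int = 10,
                      seed: int = 0) -> EvalReport:
    """Stratified k-fold CV of each preset on one shared fold partition."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = table.labels
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        small = classes[np.argmin(counts)]
        raise ValueError(
            f"class {small} has only {counts.min()} samples, fewer than "
            f"{folds} folds; use fewer folds"
        )
    n_classes = len(classes)
    X = table.matrix
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    partition = np.zeros(len(y), dtype=np.int64)
    for k, (_, te) in enumerate(splits):
        partition[te] = k
    phash = hashlib.sha256(partition.tobytes()).hexdigest()[:16]

    presets = [make_preset(p) if isinstance(p, str) else p for p in presets]
    rows, confusion = [], {}
    for preset in presets:
        pred = np.empty(len(y), dtype=np.int64)
        scores = np.empty((len(y), n_classes))
        t0 = time.perf_counter()
        for tr, te in splits:
            scaler = StandardScaler().fit(X[tr])
            est = build_estimator(preset, table.feature_dim, seed)
            est.fit(scaler.transform(X[tr]), y[tr])
            Xte = scaler.transform(X[te])
            pred[te] = est.predict(Xte)
            scores[te] = _scores(est, Xte, n_classes)
        elapsed = time.perf_counter() - t0
        rows.append(_metrics_row(preset.name, y, pred, scores, elapsed))
        confusion[preset.name] = confusion_matrix(y, pred, labels=classes)
    return EvalReport(rows, confusion, folds, seed, "cv", phash)


def holdout_evaluate(table: FeatureTable, presets, test_mask: np.ndarray,
                     seed: int = 0) -> EvalReport:
    """Train on ~test_mask rows, score on test_mask rows (80:20 holdout mode)."""
    test_mask = np.asarray(test_mask, dtype=bool)
    if test_mask.all() or not test_mask.any():
        raise ValueError("holdout mask must contain both train and test rows")
    y = table.labels
    classes = np.unique(y)
    n_classes = len(classes)
    X = table.matrix
    tr, te = ~test_mask, test_mask
    phash = hashlib.sha256(test_mask.tobytes()).hexdigest()[:16]
    presets = [make_preset(p) if isinstance(p, str) else p for p in presets]
    rows, confusion = [], {}
    scaler = StandardScaler().fit(X[tr])
    for preset in presets:
        t0 = time.perf_counter()
        est = build_estimator(preset, table.feature_dim, seed)
        est.fit(scaler.transform(X[tr]), y[tr])
        Xte = scaler.transform(X[te])
        pred = est.predict(Xte)
        scores = _scores(est, Xte, n_classes)
        elapsed = time.perf_counter() - t0
        rows.append(_metrics_row(preset.name, y[te], pred, scores, elapsed))
        confusion[preset.name] = confusion_matrix(y[te], pred, labels=classes)
    return EvalReport(rows, confusion, 1, seed, "holdout", phash)


def write_report(report: EvalReport, out_dir: str | Path) -> list[Path]:
    """One summary table plus one confusion-matrix file per classifier."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    summary = out_dir / "report.csv"
    with open(summary, "w", encoding="utf-8", newline="") as fh:
        fh.write("Classifier,Accuracy,Time,AUC,Precision Rate,Recall Rate\n")
        for r in report.rows:
            fh.write(
                f"{r['classifier']},{r['accuracy']:.2f},{r['time_s']:.2f},"
                f"{r['auc']:.4f},{r['precision']:.2f},{r['recall']:.2f}\n"
            )
    written.append(summary)
    for name, cm in report.confusion.items():
        p = out_dir / f"confusion_{name}.csv"
        np.savetxt(p, cm, fmt="%d", delimiter=",")
        written.append(p)
    return written
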