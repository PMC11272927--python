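"""Classifier training, class balancing, cross-validation and metrics.

The taste problem is a four-class task with a strongly under-represented
umami class.  Balancing follows a boosting-style oversampling scheme: the
minority classes are augmented with *copies* of their own members (no
interpolation), drawn with probabilities proportional to per-sample weights,
until every class matches the majority count.  Inside cross-validation the
oversampling is applied to the training portion of each fold only, so
synthetic copies can never leak into a validation fold.

The metric suite is the six rate metrics (ACC and weighted one-vs-rest F1,
F2, precision, recall, ROC-AUC) plus the feature count, the model complexity
(trees or support vectors) and a probability-distance term — together the
nine objectives of the evolutionary search.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (accuracy_score, fbeta_score,
                             precision_recall_fscore_support, roc_auc_score)
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .chemio import TASTE_CLASSES
from .descriptors import DescriptorTable, NormalizationParams, \
    apply_normalization, drop_sparse_features, knn_impute

BUNDLE_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family plus its hyperparameters.

    random_forest: ``n_trees`` (>= 1); svm: ``C``, ``gamma`` (> 0) and
    ``kernel`` (default rbf).
    """

    family: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("random_forest", "svm"):
            raise ValueError(f"unknown classifier family {self.family!r}")
        if self.family == "random_forest":
            if self.hyperparams.get("n_trees", 100) < 1:
                raise ValueError("n_trees must be >= 1")
        else:
            if self.hyperparams.get("C", 1.0) <= 0:
                raise ValueError("C must be > 0")
            if isinstance(self.hyperparams.get("gamma", 1.0), (int, float)) \
                    and self.hyperparams.get("gamma", 1.0) <= 0:
                raise ValueError("gamma must be > 0")


@dataclass
class MetricVector:
    """The nine-component evaluation of a candidate model."""

    acc: float
    f1: float
    f2: float
    precision: float
    recall: float
    auc: float
    n_features: int = 0
    complexity: int = 0
    distance_term: float = float("nan")
    per_class: pd.DataFrame | None = None
    flags: tuple[str, ...] = ()

    def rates(self) -> np.ndarray:
        return np.array([self.acc, self.f1, self.f2, self.precision,
                         self.recall, self.auc])


# -- balancing ---------------------------------------------------------------

def balance_oversample(X: np.ndarray, y: np.ndarray, seed: int = 0
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Oversample minority classes with weighted copies until balanced.

    Per minority class, copies are drawn with replacement with probability
    proportional to per-sample weights (initialized uniform; a drawn sample's
    weight is halved, which up-weights the not-yet-copied members of the
    minority class on the next draw and spreads the copies).  Returns
    ``(X', y', synthetic)`` where ``synthetic`` flags the appended copies.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if (counts == 0).any() or len(classes) < 2:
        raise ValueError("need at least two non-empty classes")
    majority = counts.max()
    rng = np.random.default_rng(seed)
    X_new, y_new = [X], [y]
    n_added_total = 0
    for cls, count in zip(classes, counts):
        deficit = int(majority - count)
        if deficit == 0:
            continue
        members = np.flatnonzero(y == cls)
        weights = np.ones(len(members))
        picks = np.empty(deficit, dtype=int)
        for t in range(deficit):
            p = weights / weights.sum()
            j = rng.choice(len(members), p=p)
            weights[j] *= 0.5
            picks[t] = members[j]
        X_new.append(X[picks])
        y_new.append(y[picks])
        n_added_total += deficit
    synthetic = np.concatenate([np.zeros(len(y), dtype=bool),
                                np.ones(n_added_total, dtype=bool)])
    return np.concatenate(X_new), np.concatenate(y_new), synthetic


def stratified_kfold(y: np.ndarray, k: int = 10, seed: int = 0) -> np.ndarray:
    """Fold index (0..k-1) per sample; per-class counts differ by <= 1."""
    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"smallest class has {counts.min()} members < k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(y), dtype=int)
    for f, (_, val_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        folds[val_idx] = f
    return folds


# -- metrics -----------------------------------------------------------------

def compute_metrics(y_true, y_pred, probs: np.ndarray,
                    class_order: Sequence[str] = TASTE_CLASSES) -> MetricVector:
    """ACC plus support-weighted one-vs-rest F1/F2/precision/recall/AUC.

    ``probs`` columns must follow ``class_order`` and each row sum to 1.
    Per-class metrics are attached for report tables.  AUC is NaN (flagged)
    when the truth contains a single class.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    unknown = set(np.unique(y_true)) - set(class_order)
    if unknown:
        raise ValueError(f"classes {sorted(unknown)} absent from class_order")
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (len(y_true), len(class_order)):
        raise ValueError("probability matrix shape mismatch")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")

    flags: list[str] = []
    present = [c for c in class_order if (y_true == c).any()]
    acc = float(accuracy_score(y_true, y_pred))
    prc, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=list(class_order), average="weighted",
        zero_division=0)
    f2 = fbeta_score(y_true, y_pred, beta=2, labels=list(class_order),
                     average="weighted", zero_division=0)
    if len(present) < 2:
        auc = float("nan")
        flags.append("auc-undefined")
    elif len(present) < len(class_order):
        # restrict to present classes, renormalized, for a defined OvR AUC
        cols = [list(class_order).index(c) for c in present]
        sub = probs[:, cols]
        sub = sub / sub.sum(axis=1, keepdims=True)
        if len(present) == 2:
            auc = float(roc_auc_score((y_true == present[1]).astype(int),
                                      sub[:, 1]))
        else:
            order = np.argsort(present)
            auc = float(roc_auc_score(y_true, sub[:, order],
                                      multi_class="ovr", average="weighted",
                                      labels=np.asarray(present)[order]))
        flags.append("auc-on-present-classes")
    elif len(class_order) == 2:
        auc = float(roc_auc_score((y_true == class_order[1]).astype(int),
                                  probs[:, 1]))
    else:
        order = np.argsort(np.asarray(class_order))  # sklearn wants sorted
        auc = float(roc_auc_score(y_true, probs[:, order],
                                  multi_class="ovr", average="weighted",
                                  labels=np.asarray(class_order)[order]))

    rows = []
    for i, cls in enumerate(class_order):
        truth = y_true == cls
        pred = y_pred == cls
        support = int(truth.sum())
        p_c, r_c, f1_c, _ = precision_recall_fscore_support(
            truth, pred, average="binary", zero_division=0)
        f2_c = fbeta_score(truth, pred, beta=2, zero_division=0)
        if support and support < len(y_true):
            auc_c = float(roc_auc_score(truth.astype(int), probs[:, i]))
        else:
            auc_c = float("nan")
        rows.append({"class": cls, "support": support,
                     "acc": float(accuracy_score(truth, pred)),
                     "f1": float(f1_c), "f2": float(f2_c),
                     "precision": float(p_c), "recall": float(r_c),
                     "auc": auc_c})
    per_class = pd.DataFrame(rows).set_index("class")

    return MetricVector(acc=acc, f1=float(f1), f2=float(f2),
                        precision=float(prc), recall=float(rec), auc=auc,
                        per_class=per_class, flags=tuple(flags))


# -- training ----------------------------------------------------------------

def train(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray):
    """Fit the classifier described by ``spec``; deterministic given its seed."""
    if spec.family == "random_forest":
        model = RandomForestClassifier(
            n_estimators=int(spec.hyperparams.get("n_trees", 100)),
            random_state=spec.seed, n_jobs=1)
    else:
        model = SVC(C=float(spec.hyperparams.get("C", 1.0)),
                    gamma=spec.hyperparams.get("gamma", "scale"),
                    kernel=spec.hyperparams.get("kernel", "rbf"),
                    probability=True, random_state=spec.seed)
    import warnings
    with warnings.catch_warnings():
        # pairwise-coupling probability calibration is the intended behaviour
        warnings.simplefilter("ignore", FutureWarning)
        model.fit(np.asarray(X, dtype=float), np.asarray(y))
    return model


def predict_proba(model, X: np.ndarray,
                  class_order: Sequence[str] = TASTE_CLASSES) -> np.ndarray:
    """Class probabilities reordered to ``class_order`` (absent classes -> 0)."""
    raw = model.predict_proba(np.asarray(X, dtype=float))
    out = np.zeros((raw.shape[0], len(class_order)))
    for j, cls in enumerate(model.classes_):
        out[:, list(class_order).index(cls)] = raw[:, j]
    return out


def model_complexity(model) -> int:
    """Trees for a forest; total support vectors for an SVM."""
    if isinstance(model, RandomForestClassifier):
        return int(model.n_estimators)
    if isinstance(model, SVC):
        return int(np.sum(model.n_support_))
    raise TypeError(f"unknown model type {type(model).__name__}")


@dataclass
class CVResult:
    mean: MetricVector
    sd: MetricVector
    folds: list[MetricVector]
    oof_probs: np.ndarray      # out-of-fold probabilities, original row order
    oof_pred: np.ndarray
    class_order: tuple[str, ...]


_RATE_FIELDS = ("acc", "f1", "f2", "precision", "recall", "auc")


def cross_validate(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray,
                   k: int = 10, seed: int = 0, oversample: bool = True,
                   class_order: Sequence[str] = TASTE_CLASSES) -> CVResult:
    """Stratified k-fold CV with fold-internal oversampling.

    Each fold: the training portion is balanced by
    :func:`balance_oversample` (validation rows stay untouched originals),
    the model is fitted and evaluated on the held-out portion.  Returns the
    fold metrics, their mean/SD, and the out-of-fold probability matrix.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    class_order = tuple(c for c in class_order if (y == c).any())
    folds = stratified_kfold(y, k=k, seed=seed)
    fold_metrics: list[MetricVector] = []
    oof_probs = np.zeros((len(y), len(class_order)))
    oof_pred = np.empty(len(y), dtype=y.dtype)
    for f in range(k):
        val = folds == f
        X_tr, y_tr = X[~val], y[~val]
        if oversample:
            X_tr, y_tr, _ = balance_oversample(X_tr, y_tr, seed=seed + f)
        model = train(dataclasses.replace(spec, seed=spec.seed + f), X_tr, y_tr)
        probs = predict_proba(model, X[val], class_order)
        pred = np.asarray(model.predict(X[val]))
        metrics = compute_metrics(y[val], pred, probs, class_order)
        metrics.complexity = model_complexity(model)
        fold_metrics.append(metrics)
        oof_probs[val] = probs
        oof_pred[val] = pred

    def aggregate(fn) -> MetricVector:
        values = {name: fn([getattr(m, name) for m in fold_metrics])
                  for name in _RATE_FIELDS}
        mv = MetricVector(**values)
        mv.complexity = int(round(fn([m.complexity for m in fold_metrics])))
        return mv

    mean = aggregate(lambda v: float(np.nanmean(v)))
    sd = aggregate(lambda v: float(np.nanstd(v)))
    return CVResult(mean=mean, sd=sd, folds=fold_metrics,
                    oof_probs=oof_probs, oof_pred=oof_pred,
                    class_order=class_order)


# -- the frozen final model --------------------------------------------------

@dataclass
class TastePredictor:
    """Frozen final model: selected features, normalization, classifier.

    ``predict_table`` consumes an *imputed* descriptor table over at least
    the selected features; normalization is applied with the frozen
    training parameters (out-of-range values clipped).
    """

    selected_features: list[str]
    normalization: NormalizationParams
    spec: ClassifierSpec
    model: object
    class_order: tuple[str, ...] = TASTE_CLASSES
    metadata: dict = field(default_factory=dict)

    def predict_table(self, table: DescriptorTable) -> pd.DataFrame:
        missing = set(self.selected_features) - set(table.feature_names)
        if missing:
            raise ValueError(f"table lacks selected features: {sorted(missing)}")
        if table.state == "normalized":
            X = table.data[self.selected_features].to_numpy(dtype=float)
        else:
            sub = table.data[self.selected_features]
            lo = self.normalization.minimum[self.selected_features]
            hi = self.normalization.maximum[self.selected_features]
            span = (hi - lo).replace(0.0, np.nan)
            scaled = ((sub - lo) / span).clip(0.0, 1.0)
            scaled.loc[:, (hi == lo)[hi == lo].index] = 0.0
            X = scaled.to_numpy(dtype=float)
        # a failed descriptor on a query compound maps to mid-range, not a crash
        X = np.where(np.isnan(X), 0.5, X)
        probs = predict_proba(self.model, X, self.class_order)
        pred = [self.class_order[i] for i in probs.argmax(axis=1)]
        out = pd.DataFrame(probs, columns=[f"p_{c}" for c in self.class_order],
                           index=table.compound_ids)
        out.insert(0, "predicted", pred)
        return out

    def save(self, path: str | Path) -> None:
        joblib.dump({"schema_version": BUNDLE_SCHEMA_VERSION,
                     "predictor": self}, path)

    @classmethod
    def load(cls, path: str | Path) -> "TastePredictor":
        payload = joblib.load(path)
        if payload.get("schema_version") != BUNDLE_SCHEMA_VERSION:
            raise ValueError("unsupported model bundle schema")
        return payload["predictor"]


def preprocess_raw_table(table: DescriptorTable, k_impute: int = 20,
                         max_missing_fraction: float = 0.30
                         ) -> tuple[DescriptorTable, NormalizationParams]:
    """Convenience chain raw → filtered → imputed → normalized (fit on self)."""
    filtered = drop_sparse_features(table, max_missing_fraction)
    imputed = knn_impute(filtered, k=k_impute)
    from .descriptors import fit_normalization
    params = fit_normalization(imputed)
    return apply_normalization(imputed, params), params
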