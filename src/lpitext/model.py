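"""Relation classification and evaluation.

The production classifier is L2-regularized logistic regression on the
concatenated feature blocks, with the regularization factor ``C`` and
iteration cap ``max_iter`` as the tuned hyperparameters. Continuous
blocks (semantic, syntactic, distance) are standardized to zero mean and
unit variance with statistics fitted on training data only; the binary
POS block is left untouched.

Evaluation is stratified k-fold cross-validation (tenfold by default)
over an ablation grid of cumulative feature sets x classifiers, with
per-fold metrics retained so that reported means are auditable.
Comparator classifiers (SVM, random forest, gradient boosting) are
reached through a uniform registry and never reimplemented; a missing
optional backend skips its grid cells with a logged notice.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_recall_curve
from sklearn.model_selection import StratifiedKFold

from .corpus_rules import NEGATIVE, POSITIVE
from .features import FEATURE_GROUPS, FeatureConfig, FeatureVector

__all__ = [
    "ClassifierSpec",
    "ClassifierUnavailable",
    "make_estimator",
    "Metrics",
    "metrics_from_confusion",
    "FeatureMatrix",
    "TrainedModel",
    "train",
    "predict",
    "cross_validate",
    "ablation_grid",
    "grid_search_C",
    "oof_scores",
    "pr_curve",
    "EvalReport",
    "MetricsCell",
    "save_model",
    "load_model",
    "DEFAULT_FEATURE_SETS",
]

logger = logging.getLogger(__name__)

#: Blocks that get standardized (the POS block stays binary).
CONTINUOUS_GROUPS = frozenset({"semantic", "syntactic", "distance"})

#: The four cumulative feature combinations of the ablation.
DEFAULT_FEATURE_SETS: tuple[tuple[str, ...], ...] = (
    ("semantic",),
    ("semantic", "syntactic"),
    ("semantic", "syntactic", "distance"),
    ("semantic", "syntactic", "distance", "pos"),
)


# --------------------------------------------------------------------------
# Classifier registry
# --------------------------------------------------------------------------

class ClassifierUnavailable(RuntimeError):
    """An optional comparator backend is not installed."""


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str = "logistic_regression"
    C: float = 1.0
    max_iter: int = 1000
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


def make_estimator(spec: ClassifierSpec):
    """Instantiate the scikit-learn style estimator for a spec."""
    if spec.kind == "logistic_regression":
        return LogisticRegression(C=spec.C, max_iter=spec.max_iter,
                                  random_state=spec.seed, **spec.params)
    if spec.kind == "svm":
        from sklearn.svm import SVC
        return SVC(C=spec.C, probability=True, random_state=spec.seed,
                   **spec.params)
    if spec.kind == "random_forest":
        from sklearn.ensemble import RandomForestClassifier
        return RandomForestClassifier(random_state=spec.seed, **spec.params)
    if spec.kind == "lgbm":
        try:
            from lightgbm import LGBMClassifier
        except ImportError as exc:
            raise ClassifierUnavailable("lightgbm is not installed") from exc
        return LGBMClassifier(random_state=spec.seed, verbosity=-1,
                              **spec.params)
    if spec.kind == "xgboost":
        try:
            from xgboost import XGBClassifier
        except ImportError as exc:
            raise ClassifierUnavailable("xgboost is not installed") from exc
        return XGBClassifier(random_state=spec.seed, **spec.params)
    raise ValueError(f"unknown classifier kind {spec.kind!r}")


# --------------------------------------------------------------------------
# Metrics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Metrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int
    tn: int
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1,
                "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
                "undefined": list(self.undefined)}


def metrics_from_confusion(tp: int, fp: int, fn: int, tn: int) -> Metrics:
    """Accuracy, precision, recall and F1 from confusion counts.

    A ratio with zero denominator is reported as 0 and flagged in
    ``undefined``.
    """
    for name, v in (("tp", tp), ("fp", fp), ("fn", fn), ("tn", tn)):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a non-negative integer")
    total = tp + fp + fn + tn
    undefined = []
    accuracy = (tp + tn) / total if total else 0.0
    if total == 0:
        undefined.append("accuracy")
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    if tp + fp == 0:
        undefined.append("precision")
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    if tp + fn == 0:
        undefined.append("recall")
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) else 0.0)
    if precision + recall == 0:
        undefined.append("f1")
    return Metrics(accuracy, precision, recall, f1,
                   int(tp), int(fp), int(fn), int(tn), tuple(undefined))


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    return tp, fp, fn, tn


def _label_to_int(label) -> int:
    if label in (1, 0):
        return int(label)
    if label == POSITIVE:
        return 1
    if label == NEGATIVE:
        return 0
    raise ValueError(f"unknown label {label!r}")


# --------------------------------------------------------------------------
# Feature matrices and standardization
# --------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Per-group feature matrices for a corpus, plus integer labels
    (1 = positive)."""

    blocks: dict[str, np.ndarray]
    labels: np.ndarray
    config: FeatureConfig

    def __post_init__(self) -> None:
        self.labels = np.asarray(
            [_label_to_int(l) for l in np.atleast_1d(self.labels)])
        n = len(self.labels)
        for g, m in self.blocks.items():
            if m.shape != (n, self.config.block_size(g)):
                raise ValueError(f"block {g!r} has shape {m.shape}")

    def design(self, groups: Sequence[str] | None = None
               ) -> tuple[np.ndarray, np.ndarray]:
        """Concatenated design matrix (fixed group order) and the boolean
        mask of continuous columns."""
        groups = tuple(groups) if groups is not None else self.config.groups
        ordered = [g for g in FEATURE_GROUPS if g in groups]
        X = np.hstack([self.blocks[g] for g in ordered])
        mask = np.concatenate([
            np.full(self.blocks[g].shape[1], g in CONTINUOUS_GROUPS)
            for g in ordered])
        return X, mask

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def from_examples(cls, examples: Sequence[tuple[FeatureVector, object]]
                      ) -> "FeatureMatrix":
        if not examples:
            raise ValueError("no examples")
        config = examples[0][0].config
        blocks = {g: np.stack([fv.blocks[g] for fv, _ in examples])
                  for g in config.groups}
        labels = np.array([_label_to_int(l) for _, l in examples])
        return cls(blocks=blocks, labels=labels, config=config)


def _fit_standardizer(X: np.ndarray, cont_mask: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    mean = np.zeros(X.shape[1])
    scale = np.ones(X.shape[1])
    if cont_mask.any():
        mean[cont_mask] = X[:, cont_mask].mean(axis=0)
        sd = X[:, cont_mask].std(axis=0)
        scale[cont_mask] = np.where(sd > 0, sd, 1.0)
    return mean, scale


# --------------------------------------------------------------------------
# Training and prediction
# --------------------------------------------------------------------------

def _config_signature(config: FeatureConfig, groups: Sequence[str]) -> dict:
    ordered = [g for g in FEATURE_GROUPS if g in groups]
    return {
        "groups": list(ordered),
        "block_dims": {g: config.block_size(g) for g in ordered},
        "dim": config.dim,
        "context_k": config.context_k,
        "pooling": config.pooling,
    }


@dataclass
class TrainedModel:
    estimator: object
    spec: ClassifierSpec
    signature: dict
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.scaler_mean) / self.scaler_scale


def train(
    examples: Sequence[tuple[FeatureVector, object]] | FeatureMatrix,
    spec: ClassifierSpec = ClassifierSpec(),
    groups: Sequence[str] | None = None,
) -> TrainedModel:
    """Fit a classifier on labeled feature vectors.

    Requires at least one example of each class and consistent vector
    lengths; deterministic for a fixed spec seed.
    """
    fm = (examples if isinstance(examples, FeatureMatrix)
          else FeatureMatrix.from_examples(examples))
    groups = tuple(groups) if groups is not None else fm.config.groups
    X, cont = fm.design(groups)
    y = fm.labels
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    mean, scale = _fit_standardizer(X, cont)
    est = make_estimator(spec)
    est.fit((X - mean) / scale, y)
    return TrainedModel(estimator=est, spec=spec,
                        signature=_config_signature(fm.config, groups),
                        scaler_mean=mean, scaler_scale=scale)


def predict(model: TrainedModel, fv: FeatureVector) -> tuple[str, float]:
    """Label and argmax-class probability for one feature vector.

    Refuses (rather than truncates) a vector whose feature configuration
    does not match the training configuration.
    """
    sig = _config_signature(fv.config, fv.config.groups)
    if sig != model.signature:
        raise ValueError(
            f"feature config mismatch: model trained with {model.signature}, "
            f"got {sig}")
    x = model.transform(fv.concat()[None, :])
    proba = model.estimator.predict_proba(x)[0]
    classes = list(model.estimator.classes_)
    p_pos = proba[classes.index(1)]
    if p_pos >= 0.5:
        return POSITIVE, float(p_pos)
    return NEGATIVE, float(1.0 - p_pos)


def positive_scores(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    Xs = model.transform(X)
    classes = list(model.estimator.classes_)
    return model.estimator.predict_proba(Xs)[:, classes.index(1)]


# --------------------------------------------------------------------------
# Cross-validation and the ablation grid
# --------------------------------------------------------------------------

@dataclass
class MetricsCell:
    mean: Metrics
    folds: list[Metrics]

    def validate(self, tol: float = 1e-12) -> None:
        for attr in ("accuracy", "precision", "recall", "f1"):
            fold_mean = float(np.mean([getattr(f, attr) for f in self.folds]))
            if abs(fold_mean - getattr(self.mean, attr)) > tol:
                raise AssertionError(
                    f"{attr} mean {getattr(self.mean, attr)} != "
                    f"fold mean {fold_mean}")


@dataclass
class EvalReport:
    """CV metrics per (feature set, classifier) cell, with per-fold
    detail and the fold-assignment seed."""

    cells: dict[tuple[str, str], MetricsCell]
    k: int
    seed: int
    pr_points: dict[str, list[tuple[float, float]]] = field(default_factory=dict)

    def validate(self) -> None:
        for cell in self.cells.values():
            cell.validate()

    def to_tsv(self) -> str:
        lines = ["features\tclassifier\taccuracy\tprecision\trecall\tf1"]
        for (fs, clf), cell in self.cells.items():
            m = cell.mean
            lines.append(f"{fs}\t{clf}\t{m.accuracy:.5f}\t{m.precision:.5f}"
                         f"\t{m.recall:.5f}\t{m.f1:.5f}")
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        payload = {
            "k": self.k,
            "seed": self.seed,
            "cells": [
                {"features": fs, "classifier": clf,
                 "mean": cell.mean.as_dict(),
                 "folds": [f.as_dict() for f in cell.folds]}
                for (fs, clf), cell in self.cells.items()
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _mean_metrics(folds: list[Metrics]) -> Metrics:
    return Metrics(
        accuracy=float(np.mean([f.accuracy for f in folds])),
        precision=float(np.mean([f.precision for f in folds])),
        recall=float(np.mean([f.recall for f in folds])),
        f1=float(np.mean([f.f1 for f in folds])),
        tp=sum(f.tp for f in folds), fp=sum(f.fp for f in folds),
        fn=sum(f.fn for f in folds), tn=sum(f.tn for f in folds),
        undefined=tuple(sorted({u for f in folds for u in f.undefined})),
    )


def _cv_cell(fm: FeatureMatrix, groups: Sequence[str],
             spec: ClassifierSpec, k: int, seed: int) -> MetricsCell:
    X, cont = fm.design(groups)
    y = fm.labels
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds: list[Metrics] = []
    for train_idx, test_idx in skf.split(X, y):
        mean, scale = _fit_standardizer(X[train_idx], cont)
        est = make_estimator(spec)
        est.fit((X[train_idx] - mean) / scale, y[train_idx])
        y_pred = est.predict((X[test_idx] - mean) / scale)
        folds.append(metrics_from_confusion(*_confusion(y[test_idx], y_pred)))
    return MetricsCell(mean=_mean_metrics(folds), folds=folds)


def cross_validate(
    fm: FeatureMatrix,
    spec: ClassifierSpec = ClassifierSpec(),
    k: int = 10,
    seed: int = 0,
    groups: Sequence[str] | None = None,
) -> EvalReport:
    """Stratified k-fold cross-validation; every example is tested exactly
    once and per-fold metrics are retained."""
    if len(fm) < k:
        raise ValueError(f"need at least k={k} examples, have {len(fm)}")
    if len(np.unique(fm.labels)) < 2:
        raise ValueError("both classes must be present")
    groups = tuple(groups) if groups is not None else fm.config.groups
    cell = _cv_cell(fm, groups, spec, k, seed)
    name = "+".join(g for g in FEATURE_GROUPS if g in groups)
    return EvalReport(cells={(name, spec.kind): cell}, k=k, seed=seed)


def ablation_grid(
    fm: FeatureMatrix,
    feature_sets: Sequence[Sequence[str]] | None = None,
    classifier_specs: Sequence[ClassifierSpec] | None = None,
    k: int = 10,
    seed: int = 0,
) -> EvalReport:
    """One CV cell per (feature set, classifier).

    Defaults to the four cumulative feature combinations and the built-in
    logistic regression. Cells whose optional backend is missing are
    skipped with a notice.
    """
    if feature_sets is None:
        feature_sets = [fs for fs in DEFAULT_FEATURE_SETS
                        if set(fs) <= set(fm.config.groups)]
    if classifier_specs is None:
        classifier_specs = [ClassifierSpec(seed=seed)]
    cells: dict[tuple[str, str], MetricsCell] = {}
    for fs in feature_sets:
        name = "+".join(g for g in FEATURE_GROUPS if g in fs)
        for spec in classifier_specs:
            try:
                cells[(name, spec.kind)] = _cv_cell(fm, fs, spec, k, seed)
            except ClassifierUnavailable as exc:
                logger.warning("skipping (%s, %s): %s", name, spec.kind, exc)
    return EvalReport(cells=cells, k=k, seed=seed)


def grid_search_C(
    fm: FeatureMatrix,
    Cs: Iterable[float] = (0.01, 0.1, 1.0, 10.0, 100.0),
    k: int = 10,
    seed: int = 0,
    max_iter: int = 1000,
) -> tuple[float, EvalReport]:
    """Pick the regularization factor maximizing mean CV F1 over a small
    logarithmic grid (ties break toward smaller C)."""
    best: tuple[float, float] | None = None
    reports: dict[tuple[str, str], MetricsCell] = {}
    for C in Cs:
        spec = ClassifierSpec(C=C, max_iter=max_iter, seed=seed)
        rep = cross_validate(fm, spec, k=k, seed=seed)
        cell = next(iter(rep.cells.values()))
        reports[(f"C={C:g}", spec.kind)] = cell
        score = cell.mean.f1
        if best is None or score > best[1]:
            best = (C, score)
    assert best is not None
    return best[0], EvalReport(cells=reports, k=k, seed=seed)


def oof_scores(
    fm: FeatureMatrix,
    spec: ClassifierSpec = ClassifierSpec(),
    k: int = 10,
    seed: int = 0,
    groups: Sequence[str] | None = None,
) -> np.ndarray:
    """Out-of-fold positive-class probabilities under stratified k-fold
    CV: every example is scored exactly once by a model that never saw
    it. Feeds the precision-recall curve."""
    groups = tuple(groups) if groups is not None else fm.config.groups
    X, cont = fm.design(groups)
    y = fm.labels
    scores = np.zeros(len(y))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(X, y):
        mean, scale = _fit_standardizer(X[train_idx], cont)
        est = make_estimator(spec)
        est.fit((X[train_idx] - mean) / scale, y[train_idx])
        classes = list(est.classes_)
        proba = est.predict_proba((X[test_idx] - mean) / scale)
        scores[test_idx] = proba[:, classes.index(1)]
    return scores


# --------------------------------------------------------------------------
# Precision-recall curves
# --------------------------------------------------------------------------

def pr_curve(
    model: TrainedModel,
    examples: Sequence[tuple[FeatureVector, object]] | tuple[np.ndarray, np.ndarray],
) -> list[tuple[float, float]]:
    """(recall, precision) points along the decision-threshold sweep.

    Points run from the high-threshold end (recall 0, precision defined
    as 1 by convention) toward recall 1, so recall is non-decreasing.
    Requires at least one positive example.
    """
    if isinstance(examples, tuple) and isinstance(examples[0], np.ndarray):
        X, y = examples
        y = np.asarray([_label_to_int(l) for l in y])
    else:
        fm = FeatureMatrix.from_examples(examples)
        X, _ = fm.design(model.signature["groups"])
        y = fm.labels
    if not np.any(y == 1):
        raise ValueError("held-out set must contain at least one positive")
    scores = positive_scores(model, X)
    precision, recall, _ = precision_recall_curve(y, scores)
    return [(float(r), float(p)) for r, p in zip(recall[::-1], precision[::-1])]


# --------------------------------------------------------------------------
# Serialization (versioned JSON; logistic regression only)
# --------------------------------------------------------------------------

_FORMAT_VERSION = 1


def save_model(model: TrainedModel, path: str) -> None:
    if model.spec.kind != "logistic_regression":
        raise NotImplementedError(
            "only the built-in logistic_regression kind is serializable")
    est = model.estimator
    payload = {
        "format_version": _FORMAT_VERSION,
        "kind": model.spec.kind,
        "C": model.spec.C,
        "max_iter": model.spec.max_iter,
        "seed": model.spec.seed,
        "signature": model.signature,
        "classes": [int(c) for c in est.classes_],
        "coef": est.coef_.tolist(),
        "intercept": est.intercept_.tolist(),
        "scaler_mean": model.scaler_mean.tolist(),
        "scaler_scale": model.scaler_scale.tolist(),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def load_model(path: str) -> TrainedModel:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported model format")
    spec = ClassifierSpec(kind=payload["kind"], C=payload["C"],
                          max_iter=payload["max_iter"], seed=payload["seed"])
    est = make_estimator(spec)
    est.classes_ = np.array(payload["classes"])
    est.coef_ = np.array(payload["coef"])
    est.intercept_ = np.array(payload["intercept"])
    est.n_features_in_ = est.coef_.shape[1]
    return TrainedModel(
        estimator=est, spec=spec, signature=payload["signature"],
        scaler_mean=np.array(payload["scaler_mean"]),
        scaler_scale=np.array(payload["scaler_scale"]),
    )
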