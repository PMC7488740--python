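"""Confusion-matrix metrics, ROC/AUC, cross-validation and the
independent-test harness.

Sn, Sp and ACC are reported as percentages; MCC on [-1, 1].  Cross-
validation pools per-fold test predictions into a single confusion matrix
(so TP+FN equals the total positive count) and additionally reports
per-fold metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FN/FP/TN counts with positives = label 1."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_predictions(
        cls, y_true: np.ndarray, y_pred: np.ndarray
    ) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        )

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn


def compute_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Sn/Sp/ACC (percent) and MCC from confusion counts.

    MCC is defined as 0 when any factor of its denominator is 0.
    """
    tp, fn, fp, tn = counts.tp, counts.fn, counts.fp, counts.tn
    if tp + fn == 0:
        raise ValueError("no positive samples (TP+FN = 0)")
    if tn + fp == 0:
        raise ValueError("no negative samples (TN+FP = 0)")
    sn = tp / (tp + fn) * 100.0
    sp = tn / (tn + fp) * 100.0
    acc = (tp + tn) / (tp + fn + fp + tn) * 100.0
    denom = (tp + fn) * (tp + fp) * (tn + fn) * (tn + fp)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return {"sn": sn, "sp": sp, "acc": acc, "mcc": mcc}


def roc_auc(
    labels: np.ndarray, scores: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve (FPR, TPR over all distinct thresholds) and trapezoidal AUC."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes present")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    fpr, tpr, _ = roc_curve(labels, scores)
    return fpr, tpr, float(_auc(fpr, tpr))


@dataclass
class EvalReport:
    """Evaluation summary: counts, Eq-style metrics and the ROC curve."""

    counts: ConfusionCounts
    sn: float
    sp: float
    acc: float
    mcc: float
    fpr: np.ndarray = field(default_factory=lambda: np.array([]))
    tpr: np.ndarray = field(default_factory=lambda: np.array([]))
    auc: float = float("nan")

    def to_row(self) -> dict[str, float]:
        return {
            "sn": self.sn,
            "sp": self.sp,
            "acc": self.acc,
            "mcc": self.mcc,
            "auc": self.auc,
            "tp": self.counts.tp,
            "fn": self.counts.fn,
            "fp": self.counts.fp,
            "tn": self.counts.tn,
        }


def evaluate_predictions(
    y_true: np.ndarray,
    probabilities: np.ndarray,
    threshold: float = 0.5,
) -> EvalReport:
    """Build an :class:`EvalReport` from positive-class probabilities."""
    y_true = np.asarray(y_true, dtype=int)
    probabilities = np.asarray(probabilities, dtype=float)
    y_pred = (probabilities >= threshold).astype(int)
    counts = ConfusionCounts.from_predictions(y_true, y_pred)
    m = compute_metrics(counts)
    fpr, tpr, auc_val = roc_auc(y_true, probabilities)
    return EvalReport(
        counts=counts, fpr=fpr, tpr=tpr, auc=auc_val, **m
    )


def kfold_cv(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    svm_config: Optional["SvmConfig"] = None,
    seed: int = 0,
) -> tuple[EvalReport, list[EvalReport]]:
    """Stratified k-fold CV of the SVM; returns the pooled report
    (test-fold predictions concatenated) and per-fold reports."""
    from .classifier import SvmConfig, predict, train

    if svm_config is None:
        svm_config = SvmConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if folds < 2:
        raise ValueError(f"folds must be >= 2, got {folds}")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pooled_y = np.empty_like(y)
    pooled_p = np.empty(len(y), dtype=float)
    fold_reports = []
    for train_idx, test_idx in skf.split(X, y):
        model = train(X[train_idx], y[train_idx], svm_config, seed=seed)
        proba, _ = predict(model, X[test_idx])
        pooled_y[test_idx] = y[test_idx]
        pooled_p[test_idx] = proba
        fold_reports.append(
            evaluate_predictions(y[test_idx], proba, svm_config.threshold)
        )
    pooled = evaluate_predictions(pooled_y, pooled_p, svm_config.threshold)
    return pooled, fold_reports


@dataclass
class PipelineConfig:
    """Knobs of the full encode -> rank -> select -> tune -> train pipeline.

    ``selection_stride`` > 1 coarsens backward elimination for quick runs;
    ``c_grid``/``gamma_grid`` of None use the full default grids.
    """

    encoder: Optional["EncoderConfig"] = None
    boosting: Optional["BoostingConfig"] = None
    select: bool = True
    selection_folds: int = 10
    selection_stride: int = 1
    min_size: int = 1
    grid_folds: int = 10
    c_grid: Optional[np.ndarray] = None
    gamma_grid: Optional[np.ndarray] = None
    threshold: float = 0.5


def independent_test(
    train_set: "SampleSet",
    test_set: "SampleSet",
    config: Optional[PipelineConfig] = None,
    seed: int = 0,
) -> tuple[EvalReport, "TrainedModel"]:
    """Fit the full pipeline on the training windows only and report on the
    held-out test windows.  Overlapping sample ids raise a leakage error."""
    from .classifier import SvmConfig, default_grid, grid_search, predict, train
    from .feature_encoding import encode_samples, feature_matrix
    from .feature_selection import backward_eliminate
    from .importance_ranking import rank_features, train_ranker

    if config is None:
        config = PipelineConfig()
    overlap = set(train_set.ids) & set(test_set.ids)
    if overlap:
        raise ValueError(
            f"train/test leakage: {len(overlap)} shared sample id(s), "
            f"e.g. {sorted(overlap)[:3]}"
        )

    X_train, y_train, _ = feature_matrix(encode_samples(train_set, config.encoder))
    X_test, y_test, _ = feature_matrix(encode_samples(test_set, config.encoder))

    ranker = train_ranker(X_train, y_train, config.boosting, seed=seed)
    importance_type = (
        config.boosting.importance_type if config.boosting else "weight"
    )
    ranking = rank_features(ranker, importance_type)

    if config.select:
        selection = backward_eliminate(
            X_train,
            y_train,
            ranking,
            cv_folds=config.selection_folds,
            min_size=config.min_size,
            stride=config.selection_stride,
            seed=seed,
        )
        subset = selection.best_subset
    else:
        subset = np.arange(X_train.shape[1])

    c_grid, gamma_grid = default_grid()
    if config.c_grid is not None:
        c_grid = config.c_grid
    if config.gamma_grid is not None:
        gamma_grid = config.gamma_grid
    svm_config = grid_search(
        X_train[:, subset],
        y_train,
        c_grid=c_grid,
        gamma_grid=gamma_grid,
        cv_folds=config.grid_folds,
        seed=seed,
    )
    svm_config = SvmConfig(
        C=svm_config.C, gamma=svm_config.gamma, threshold=config.threshold
    )
    model = train(
        X_train[:, subset], y_train, svm_config, seed=seed, retained_dims=subset
    )
    proba, _ = predict(model, X_test[:, subset])
    return evaluate_predictions(y_test, proba, config.threshold), model


def report_frame(reports: dict[str, EvalReport]) -> pd.DataFrame:
    """Machine-readable summary: one row per experiment."""
    rows = [{"dataset": name, **rep.to_row()} for name, rep in reports.items()]
    return pd.DataFrame(rows)
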