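"""Backward elimination over an importance ranking.

The lowest-ranked retained dimension is dropped one step at a time (or
``stride`` at a time for quick runs) and each retained prefix is scored by
stratified cross-validation with an RBF-kernel SVM under fixed
hyperparameters (C=1, gamma = 1/subset size).  Fold assignment is fixed by
the seed and shared across all steps so trace values are comparable.

The winning subset maximizes mean CV accuracy; ties are broken by higher
MCC, then by smaller subset size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .evaluation import ConfusionCounts, compute_metrics, roc_auc
from .importance_ranking import ImportanceRanking

METRIC_KEYS = ("sn", "sp", "acc", "mcc", "auc")


def evaluate_subset(
    X: np.ndarray,
    y: np.ndarray,
    subset: np.ndarray,
    cv_folds: int = 10,
    seed: int = 0,
    C: float = 1.0,
    gamma: "float | str" = "auto",
) -> dict[str, float]:
    """Mean Sn/Sp/ACC/MCC/AUC over stratified CV folds for one subset.

    ``gamma='auto'`` means 1 / (number of retained dimensions).  AUC is
    computed from SVM decision values (no probability calibration, for
    speed).  Deterministic given the seed.
    """
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        raise ValueError("empty feature subset")
    if cv_folds < 2:
        raise ValueError(f"cv_folds must be >= 2, got {cv_folds}")
    Xs = np.asarray(X, dtype=float)[:, subset]
    y = np.asarray(y, dtype=int)

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    fold_metrics: list[dict[str, float]] = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(Xs, y)):
        for name, idx in (("train", train_idx), ("test", test_idx)):
            if len(np.unique(y[idx])) < 2:
                raise ValueError(
                    f"fold {fold}: {name} split does not contain both classes"
                )
        clf = SVC(kernel="rbf", C=C, gamma=gamma)
        clf.fit(Xs[train_idx], y[train_idx])
        pred = clf.predict(Xs[test_idx])
        scores = clf.decision_function(Xs[test_idx])
        counts = ConfusionCounts.from_predictions(y[test_idx], pred)
        m = compute_metrics(counts)
        _, _, m["auc"] = roc_auc(y[test_idx], scores)
        fold_metrics.append(m)
    return {
        key: float(np.mean([m[key] for m in fold_metrics])) for key in METRIC_KEYS
    }


@dataclass
class SelectionResult:
    """Outcome of backward elimination.

    ``best_subset`` is the retained 0-based dimension set (a prefix of
    the importance order); ``trace`` has one row per evaluated size.
    """

    best_subset: np.ndarray
    trace: pd.DataFrame
    criterion: str = "acc"
    order: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def best_size(self) -> int:
        return len(self.best_subset)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.trace.to_csv(out / "trace.tsv", sep="\t", index=False)
        pd.Series([f"D{i + 1}" for i in self.best_subset]).to_csv(
            out / "retained.txt", index=False, header=False
        )


def backward_eliminate(
    X: np.ndarray,
    y: np.ndarray,
    ranking: ImportanceRanking,
    cv_folds: int = 10,
    min_size: int = 1,
    stride: int = 1,
    seed: int = 0,
    criterion: str = "acc",
) -> SelectionResult:
    """Evaluate the ranked prefixes of sizes n, n-stride, ..., >= min_size
    and return the best one plus the full trace."""
    X = np.asarray(X, dtype=float)
    n_dims = X.shape[1]
    if ranking.n_dims != n_dims:
        raise ValueError(
            f"ranking covers {ranking.n_dims} dimensions, matrix has {n_dims}"
        )
    if not (1 <= min_size <= n_dims):
        raise ValueError(f"min_size must be in [1, {n_dims}], got {min_size}")
    if criterion not in METRIC_KEYS:
        raise ValueError(f"unknown criterion {criterion!r}")

    sizes = list(range(n_dims, min_size - 1, -stride))
    rows = []
    for size in sizes:
        metrics = evaluate_subset(
            X, y, ranking.top(size), cv_folds=cv_folds, seed=seed
        )
        rows.append({"size": size, **metrics})
    trace = pd.DataFrame(rows)

    # argmax on criterion; ties -> higher MCC, then smaller subset
    best_row = max(
        trace.itertuples(index=False),
        key=lambda r: (getattr(r, criterion), r.mcc, -r.size),
    )
    return SelectionResult(
        best_subset=ranking.top(int(best_row.size)),
        trace=trace,
        criterion=criterion,
        order=ranking.order.copy(),
    )
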