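"""RBF-kernel SVM with probability outputs and log2 grid search.

The default search grids are C in {2^-5, 2^-4, ..., 2^10} and gamma in
{2^-15, ..., 2^2} (multiplicative steps of 2).  The winning pair maximizes
mean CV accuracy; ties prefer smaller C, then smaller gamma.  Probability
outputs come from sigmoid calibration on decision values (the library's
internal cross-validated Platt scaling), seed-fixed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import joblib
import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC


@dataclass(frozen=True)
class SvmConfig:
    C: float = 1.0
    gamma: float | str = "auto"
    kernel: str = "rbf"
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if isinstance(self.C, (int, float)) and self.C <= 0:
            raise ValueError(f"C must be positive, got {self.C}")
        if not (0 < self.threshold < 1):
            raise ValueError(f"threshold must be in (0,1), got {self.threshold}")


def default_grid() -> tuple[np.ndarray, np.ndarray]:
    """(C candidates, gamma candidates) as log2-spaced grids."""
    return (
        2.0 ** np.arange(-5, 11),
        2.0 ** np.arange(-15, 3),
    )


def _check_two_classes(y: np.ndarray) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training data contains a single class")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    c_grid: Optional[np.ndarray] = None,
    gamma_grid: Optional[np.ndarray] = None,
    cv_folds: int = 10,
    seed: int = 0,
) -> SvmConfig:
    """Pick the (C, gamma) pair with the best mean CV accuracy."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _check_two_classes(y)
    if cv_folds < 2:
        raise ValueError(f"cv_folds must be >= 2, got {cv_folds}")
    if c_grid is None or gamma_grid is None:
        dc, dg = default_grid()
        c_grid = dc if c_grid is None else c_grid
        gamma_grid = dg if gamma_grid is None else gamma_grid
    c_grid = np.sort(np.asarray(c_grid, dtype=float))
    gamma_grid = np.sort(np.asarray(gamma_grid, dtype=float))
    if c_grid.size == 0 or gamma_grid.size == 0:
        raise ValueError("empty hyperparameter grid")

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best: tuple[float, float, float] | None = None  # (acc, C, gamma)
    best_acc = -1.0
    for C in c_grid:
        for gamma in gamma_grid:
            correct = 0
            for train_idx, test_idx in splits:
                clf = SVC(kernel="rbf", C=C, gamma=gamma)
                clf.fit(X[train_idx], y[train_idx])
                correct += int(np.sum(clf.predict(X[test_idx]) == y[test_idx]))
            acc = correct / len(y)
            # strict improvement keeps the smallest C then gamma on ties
            if acc > best_acc:
                best_acc = acc
                best = (acc, float(C), float(gamma))
    assert best is not None
    return SvmConfig(C=best[1], gamma=best[2])


@dataclass
class TrainedModel:
    """A fitted SVM plus the feature subset and provenance it requires."""

    config: SvmConfig
    estimator: CalibratedClassifierCV
    retained_dims: np.ndarray
    seed: int
    fingerprint: str

    @property
    def n_features(self) -> int:
        return len(self.retained_dims)

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain a TrainedModel")
        return model


def _fingerprint(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:16]


def train(
    X: np.ndarray,
    y: np.ndarray,
    config: Optional[SvmConfig] = None,
    seed: int = 0,
    retained_dims: Optional[np.ndarray] = None,
) -> TrainedModel:
    """Fit the RBF SVM with calibrated probability outputs."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _check_two_classes(y)
    if config is None:
        config = SvmConfig()
    if retained_dims is None:
        retained_dims = np.arange(X.shape[1])
    retained_dims = np.asarray(retained_dims, dtype=int)
    if len(retained_dims) != X.shape[1]:
        raise ValueError(
            f"matrix has {X.shape[1]} columns but {len(retained_dims)} "
            "retained dimensions were declared"
        )
    # sigmoid (Platt) calibration of decision values, cross-validated on
    # the training data; StratifiedKFold without shuffling keeps it
    # deterministic for a fixed training set
    _, counts = np.unique(y, return_counts=True)
    inner_cv = int(min(5, counts.min()))
    clf = CalibratedClassifierCV(
        SVC(kernel="rbf", C=config.C, gamma=config.gamma),
        method="sigmoid",
        cv=inner_cv,
        ensemble=False,
    )
    clf.fit(X, y)
    return TrainedModel(
        config=config,
        estimator=clf,
        retained_dims=retained_dims,
        seed=seed,
        fingerprint=_fingerprint(X, y),
    )


def predict(
    model: TrainedModel, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Positive-class probability and thresholded label per sample.

    A probability exactly at the threshold is called positive.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"feature matrix has {X.shape[1] if X.ndim == 2 else 'bad'} "
            f"columns; model requires {model.n_features}"
        )
    pos_col = int(np.where(model.estimator.classes_ == 1)[0][0])
    proba = model.estimator.predict_proba(X)[:, pos_col]
    labels = (proba >= model.config.threshold).astype(int)
    return proba, labels
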