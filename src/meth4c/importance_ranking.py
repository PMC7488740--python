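"""Boosted-tree feature importance and the induced ranking.

Importance is extracted from a fitted gradient-boosted tree ensemble by
traversing every tree:

* ``weight`` (default): number of times a dimension is used as a split,
* ``gain``: total impurity reduction contributed by its splits,
* ``cover``: total number of (weighted) samples routed through its splits.

Dimensions never used in any split score 0 and rank after all
positive-score dimensions; ties are broken by ascending dimension index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.exceptions import NotFittedError
from sklearn.utils.validation import check_is_fitted

IMPORTANCE_TYPES = ("weight", "gain", "cover")


@dataclass
class BoostingConfig:
    """Hyperparameters of the importance-scoring ensemble."""

    n_estimators: int = 100
    max_depth: int = 6
    learning_rate: float = 0.3
    importance_type: str = "weight"

    def __post_init__(self) -> None:
        if self.importance_type not in IMPORTANCE_TYPES:
            raise ValueError(
                f"importance_type must be one of {IMPORTANCE_TYPES}, "
                f"got {self.importance_type!r}"
            )


def train_ranker(
    X: np.ndarray,
    y: np.ndarray,
    config: BoostingConfig | None = None,
    seed: int = 42,
) -> GradientBoostingClassifier:
    """Fit the boosted-tree ensemble used for importance scoring.

    Deterministic given the seed (single-threaded exact tree construction).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.size == 0:
        raise ValueError("empty feature matrix")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training data contains a single class")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    if np.isnan(X).any():
        raise ValueError("feature matrix contains missing values")
    if config is None:
        config = BoostingConfig()
    model = GradientBoostingClassifier(
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        learning_rate=config.learning_rate,
        random_state=seed,
    )
    model.fit(X, y)
    return model


def _tree_scores(model: GradientBoostingClassifier, kind: str) -> np.ndarray:
    scores = np.zeros(model.n_features_in_)
    for stage in model.estimators_:
        for est in stage:
            tree = est.tree_
            split = tree.children_left != -1
            feats = tree.feature[split]
            if kind == "weight":
                np.add.at(scores, feats, 1.0)
            elif kind == "cover":
                np.add.at(scores, feats, tree.weighted_n_node_samples[split])
            else:  # gain: weighted impurity decrease per split
                left = tree.children_left[split]
                right = tree.children_right[split]
                n = tree.weighted_n_node_samples
                gain = (
                    n[split] * tree.impurity[split]
                    - n[left] * tree.impurity[left]
                    - n[right] * tree.impurity[right]
                )
                np.add.at(scores, feats, gain)
    return scores


@dataclass
class ImportanceRanking:
    """Per-dimension importance scores and the induced total order.

    ``order`` holds 0-based dimension indices from highest to lowest
    score, ties broken by ascending index.
    """

    scores: np.ndarray
    importance_type: str = "weight"
    order: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if np.any(self.scores < 0):
            raise ValueError("importance scores must be non-negative")
        # stable argsort on negated scores: descending score, ascending index
        self.order = np.argsort(-self.scores, kind="stable")

    @property
    def n_dims(self) -> int:
        return len(self.scores)

    def top(self, k: int) -> np.ndarray:
        """0-based indices of the k highest-ranked dimensions."""
        return self.order[:k]

    def to_frame(self) -> pd.DataFrame:
        """Two-column (dimension, score) frame sorted by rank; dimensions
        are 1-based D-labels matching the feature-table columns."""
        return pd.DataFrame(
            {
                "dimension": [f"D{i + 1}" for i in self.order],
                "score": self.scores[self.order],
            }
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path: str | Path, importance_type: str = "weight") -> "ImportanceRanking":
        frame = pd.read_csv(path, sep="\t")
        idx = frame["dimension"].str.lstrip("D").astype(int).to_numpy() - 1
        scores = np.zeros(idx.max() + 1)
        scores[idx] = frame["score"].to_numpy(dtype=float)
        return cls(scores=scores, importance_type=importance_type)


def rank_features(
    ranker: GradientBoostingClassifier, importance_type: str = "weight"
) -> ImportanceRanking:
    """Extract an :class:`ImportanceRanking` from a fitted ensemble."""
    if importance_type not in IMPORTANCE_TYPES:
        raise ValueError(
            f"importance_type must be one of {IMPORTANCE_TYPES}, "
            f"got {importance_type!r}"
        )
    try:
        check_is_fitted(ranker)
    except NotFittedError as exc:
        raise ValueError("ranker is not fitted") from exc
    scores = _tree_scores(ranker, importance_type)
    return ImportanceRanking(scores=scores, importance_type=importance_type)
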