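"""Synthetic cytosine-centred window sets with controllable positional signal.

Positives are drawn from a per-position distribution interpolated between
a background composition and a motif; negatives come from the background.
The centre position is C with probability 1 for both classes, so the sets
mirror the structure of curated 4mC benchmarks.  A direct feature-table
generator (Gaussian class-shift columns) is also provided for testing the
selection and classification stages without the encoders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequence_io import ConfigurationError, DnaSample, SampleSet

NUCLEOTIDES = "ACGT"
DEFAULT_WINDOW_LENGTH = 41


def _check_probs(p: np.ndarray, name: str) -> None:
    if np.any(p < 0) or not np.allclose(p.sum(axis=-1), 1.0):
        raise ConfigurationError(f"{name} is not a valid probability vector")


@dataclass
class MotifModel:
    """Per-position nucleotide distributions for the positive class.

    ``effect_strength`` in [0, 1] interpolates the positive-class
    distribution from ``background`` (0) to ``position_weights`` (1).
    """

    position_weights: np.ndarray  # (L, 4) over (A, C, G, T)
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    effect_strength: float = 1.0

    def __post_init__(self) -> None:
        self.position_weights = np.asarray(self.position_weights, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        _check_probs(self.position_weights, "position_weights")
        _check_probs(self.background, "background")
        if not (0.0 <= self.effect_strength <= 1.0):
            raise ConfigurationError(
                f"effect_strength must be in [0,1], got {self.effect_strength}"
            )

    @property
    def window_length(self) -> int:
        return self.position_weights.shape[0]

    def positive_weights(self) -> np.ndarray:
        """Interpolated per-position distribution for positives."""
        e = self.effect_strength
        return (1.0 - e) * self.background[None, :] + e * self.position_weights


def default_motif(
    window_length: int = DEFAULT_WINDOW_LENGTH,
    effect_strength: float = 1.0,
    bias: float = 0.85,
) -> MotifModel:
    """Motif biasing the 5 positions flanking the centre.

    The two positions upstream prefer G, the two downstream prefer A and
    the +3 position prefers T, with probability ``bias`` each; all other
    positions are uniform.
    """
    if window_length % 2 == 0:
        raise ConfigurationError("window_length must be odd")
    weights = np.full((window_length, 4), 0.25)
    center = window_length // 2
    rest = (1.0 - bias) / 3.0

    def biased(base: str) -> np.ndarray:
        p = np.full(4, rest)
        p[NUCLEOTIDES.index(base)] = bias
        return p

    for offset, base in ((-2, "G"), (-1, "G"), (1, "A"), (2, "A"), (3, "T")):
        pos = center + offset
        if 0 <= pos < window_length:
            weights[pos] = biased(base)
    return MotifModel(position_weights=weights, effect_strength=effect_strength)


def generate(
    n_pos: int,
    n_neg: int,
    motif: MotifModel | None = None,
    window_length: int = DEFAULT_WINDOW_LENGTH,
    seed: int = 0,
) -> SampleSet:
    """Draw a labeled, centre-C window set (positives first)."""
    if n_pos < 0 or n_neg < 0:
        raise ConfigurationError("sample counts must be non-negative")
    if window_length % 2 == 0:
        raise ConfigurationError("window_length must be odd")
    if motif is None:
        motif = default_motif(window_length)
    if motif.window_length != window_length:
        raise ConfigurationError(
            f"motif covers {motif.window_length} positions, "
            f"window_length is {window_length}"
        )
    rng = np.random.default_rng(seed)
    center = window_length // 2
    pos_weights = motif.positive_weights()
    neg_weights = np.tile(motif.background, (window_length, 1))

    bases = np.array(list(NUCLEOTIDES))
    samples = []
    for label, n, weights, tag in (
        (1, n_pos, pos_weights, "pos"),
        (0, n_neg, neg_weights, "neg"),
    ):
        if n == 0:
            continue
        codes = np.column_stack(
            [rng.choice(4, size=n, p=weights[p]) for p in range(window_length)]
        )
        codes[:, center] = NUCLEOTIDES.index("C")
        for i, row in enumerate(bases[codes]):
            samples.append(
                DnaSample(
                    id=f"{tag}_{i + 1}", sequence="".join(row), label=label
                )
            )
    return SampleSet(samples=samples, window_length=window_length)


def generate_feature_table(
    n: int,
    n_informative: int,
    n_noise: int,
    effect: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Balanced Gaussian feature table for selection/classifier tests.

    Informative columns shift their class-1 mean by ``effect`` (in
    within-class standard deviations); noise columns are N(0,1) for both
    classes.  Informative columns come first.  Returns (X, y).
    """
    if n < 4 or n % 2 != 0:
        raise ConfigurationError("n must be an even integer >= 4")
    if n_informative < 0 or n_noise < 0:
        raise ConfigurationError("dimension counts must be non-negative")
    rng = np.random.default_rng(seed)
    d = n_informative + n_noise
    y = np.repeat([1, 0], n // 2)
    X = rng.standard_normal((n, d))
    X[y == 1, :n_informative] += effect
    return X, y


def to_frame(X: np.ndarray, y: np.ndarray, prefix: str = "s") -> pd.DataFrame:
    """Wrap a matrix into the standard feature-table layout."""
    frame = pd.DataFrame(
        X, columns=[f"D{i + 1}" for i in range(X.shape[1])]
    )
    frame.insert(0, "label", y)
    frame.insert(0, "id", [f"{prefix}{i + 1}" for i in range(len(y))])
    return frame
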