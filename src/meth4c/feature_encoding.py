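"""Five sequence-encoder families and their assembly into one feature vector.

For a 41-nt window with the default configuration the assembled vector has
292 dimensions laid out as::

    OHB    D1-D164    per-position one-hot bits
    SNF    D165-D205  cumulative nucleotide density
    KNF    D206-D225  k-mer frequencies, k in {1, 2}
    KSNPF  D226-D273  k-spaced pair frequencies, k in {1, 2, 3}
    PseDNC D274-D292  dinucleotide composition + 3 tier correlations
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .sequence_io import ConfigurationError, DnaSample, SampleSet

NUCLEOTIDES = "ACGT"
#: One-hot bit assignment per nucleotide (bit order A, G, T, C).
OHB_CODE = {
    "A": (1.0, 0.0, 0.0, 0.0),
    "G": (0.0, 1.0, 0.0, 0.0),
    "T": (0.0, 0.0, 1.0, 0.0),
    "C": (0.0, 0.0, 0.0, 1.0),
}
DINUCLEOTIDES = ["".join(p) for p in itertools.product(NUCLEOTIDES, repeat=2)]

_PROPERTY_FILE = "dinucleotide_properties.tsv"


def _as_sequence(sample: "DnaSample | str") -> str:
    return sample.sequence if isinstance(sample, DnaSample) else sample


def load_property_table(path: Optional[str | Path] = None) -> pd.DataFrame:
    """Load the dinucleotide physico-chemical property table.

    Returns a (n_properties x 16) frame indexed by property name with
    columns AA..TT, each row standardized to zero mean and unit variance
    across the 16 dinucleotides.
    """
    if path is None:
        source = resources.files("meth4c").joinpath("data", _PROPERTY_FILE)
        with resources.as_file(source) as p:
            table = pd.read_csv(p, sep="\t", comment="#", index_col=0)
    else:
        table = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if list(table.columns) != DINUCLEOTIDES:
        raise ConfigurationError(
            f"property table columns must be {DINUCLEOTIDES} in order"
        )
    values = table.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    std = values.std(axis=1, keepdims=True)
    if np.any(std == 0):
        raise ConfigurationError("property table contains a constant row")
    return pd.DataFrame(
        (values - mean) / std, index=table.index, columns=table.columns
    )


@dataclass
class PseDncParams:
    """Parameters of the pseudo dinucleotide composition encoder.

    ``lam`` is the number of correlation tiers and ``w`` the weight factor;
    ``property_table`` holds standardized property values per dinucleotide
    (rows = properties, columns = the 16 dinucleotides in lexicographic
    order).
    """

    lam: int = 3
    w: float = 0.05
    property_table: pd.DataFrame = field(default_factory=load_property_table)

    def __post_init__(self) -> None:
        if self.lam < 1:
            raise ConfigurationError(f"lambda must be >= 1, got {self.lam}")
        if not (0 < self.w):
            raise ConfigurationError(f"weight factor must be positive, got {self.w}")

    @property
    def n_properties(self) -> int:
        return self.property_table.shape[0]


def encode_ohb(sample: "DnaSample | str") -> np.ndarray:
    """One-hot binary feature: 4 bits per position, length 4L."""
    seq = _as_sequence(sample)
    out = np.empty(4 * len(seq))
    for i, base in enumerate(seq):
        out[4 * i : 4 * i + 4] = OHB_CODE[base]
    return out


def encode_snf(sample: "DnaSample | str") -> np.ndarray:
    """Sequential nucleotide frequency (nucleotide density), length L.

    Entry i is the frequency of the nucleotide at position i among
    positions 1..i, so the first entry is always 1.
    """
    seq = _as_sequence(sample)
    out = np.empty(len(seq))
    counts = {b: 0 for b in NUCLEOTIDES}
    for i, base in enumerate(seq):
        counts[base] += 1
        out[i] = counts[base] / (i + 1)
    return out


def encode_knf(
    sample: "DnaSample | str", k_values: Sequence[int] = (1, 2)
) -> np.ndarray:
    """k-nucleotide (k-mer) frequencies, 4^k dimensions per k.

    For each k (ascending) the 4^k frequencies are reported in
    lexicographic order over (A, C, G, T); each k-block sums to 1 since
    the denominator S-k+1 equals the number of windows counted.
    """
    seq = _as_sequence(sample)
    blocks = []
    for k in sorted(set(k_values)):
        if k < 1 or k > len(seq):
            raise ConfigurationError(
                f"KNF k={k} invalid for sequence length {len(seq)}"
            )
        kmers = ["".join(p) for p in itertools.product(NUCLEOTIDES, repeat=k)]
        index = {m: j for j, m in enumerate(kmers)}
        counts = np.zeros(len(kmers))
        for i in range(len(seq) - k + 1):
            counts[index[seq[i : i + k]]] += 1
        blocks.append(counts / (len(seq) - k + 1))
    return np.concatenate(blocks)


def encode_ksnpf(
    sample: "DnaSample | str", k_values: Sequence[int] = (1, 2, 3)
) -> np.ndarray:
    """k-spaced nucleotide pair frequencies, 16 dimensions per k.

    A k-spaced pair is two nucleotides separated by exactly k positions
    (e.g. AXXT for k=2).  Pairs are ordered lexicographically over
    (A,C,G,T) x (A,C,G,T); the denominator S-k-1 equals the number of
    valid pair positions, so each 16-entry block sums to 1.
    """
    seq = _as_sequence(sample)
    blocks = []
    for k in sorted(set(k_values)):
        if k < 1 or k > len(seq) - 2:
            raise ConfigurationError(
                f"KSNPF k={k} invalid for sequence length {len(seq)}"
            )
        index = {p: j for j, p in enumerate(DINUCLEOTIDES)}
        counts = np.zeros(16)
        for i in range(len(seq) - k - 1):
            counts[index[seq[i] + seq[i + k + 1]]] += 1
        blocks.append(counts / (len(seq) - k - 1))
    return np.concatenate(blocks)


def encode_psednc(
    sample: "DnaSample | str", params: Optional[PseDncParams] = None
) -> np.ndarray:
    """Pseudo dinucleotide composition, length 16 + lambda.

    The head holds the 16 normalized dinucleotide frequencies f_k and the
    tail the lambda tier-correlation terms theta_j, both divided by
    ``sum(f) + w * sum(theta)`` so the whole vector sums to 1.  The
    correlation of a j-tier pair of dinucleotides is the mean squared
    difference of their standardized property values over all properties.
    """
    if params is None:
        params = PseDncParams()
    seq = _as_sequence(sample)
    L = len(seq)
    if params.lam >= L:
        raise ConfigurationError(
            f"lambda={params.lam} must be < sequence length {L}"
        )

    index = {p: j for j, p in enumerate(DINUCLEOTIDES)}
    dinuc_idx = np.array([index[seq[i : i + 2]] for i in range(L - 1)])
    counts = np.bincount(dinuc_idx, minlength=16).astype(float)
    f = counts / counts.sum()

    # prop[:, i] = standardized property values of the dinucleotide at i
    prop = params.property_table.to_numpy()[:, dinuc_idx]
    theta = np.empty(params.lam)
    for j in range(1, params.lam + 1):
        diffs = prop[:, : L - 1 - j] - prop[:, j:]
        theta[j - 1] = np.mean((diffs**2).mean(axis=0))

    denom = f.sum() + params.w * theta.sum()
    return np.concatenate([f / denom, params.w * theta / denom])


@dataclass
class EncoderConfig:
    """Configuration of the assembled feature space."""

    knf_k: tuple[int, ...] = (1, 2)
    ksnpf_k: tuple[int, ...] = (1, 2, 3)
    psednc: PseDncParams = field(default_factory=PseDncParams)


@dataclass(frozen=True)
class FeatureLayout:
    """Contiguous 1-based dimension ranges of the encoder families.

    ``blocks`` is an ordered list of ``(family, start, end, descriptors)``
    where ``descriptors`` names each dimension in the block.
    """

    blocks: tuple[tuple[str, int, int, tuple[str, ...]], ...]

    @property
    def total_dim(self) -> int:
        return self.blocks[-1][2]

    @property
    def families(self) -> list[str]:
        return [b[0] for b in self.blocks]

    def block_range(self, family: str) -> tuple[int, int]:
        """1-based inclusive (start, end) dimensions of a family."""
        for name, start, end, _ in self.blocks:
            if name == family:
                return start, end
        raise KeyError(family)

    def dimension_names(self) -> list[str]:
        return [f"D{i}" for i in range(1, self.total_dim + 1)]

    def descriptors(self) -> list[str]:
        out: list[str] = []
        for _, _, _, desc in self.blocks:
            out.extend(desc)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for family, start, end, desc in self.blocks:
            for offset, d in enumerate(desc):
                rows.append((f"D{start + offset}", family, d))
        return pd.DataFrame(rows, columns=["dimension", "family", "descriptor"])


def build_layout(window_length: int = 41, config: Optional[EncoderConfig] = None) -> FeatureLayout:
    if config is None:
        config = EncoderConfig()
    L = window_length
    blocks = []
    pos = 1

    desc = tuple(
        f"pos{i + 1}:{b}" for i in range(L) for b in ("A", "G", "T", "C")
    )
    blocks.append(("OHB", pos, pos + 4 * L - 1, desc))
    pos += 4 * L

    desc = tuple(f"pos{i + 1}" for i in range(L))
    blocks.append(("SNF", pos, pos + L - 1, desc))
    pos += L

    knf_desc: list[str] = []
    for k in sorted(set(config.knf_k)):
        knf_desc.extend(
            "".join(p) for p in itertools.product(NUCLEOTIDES, repeat=k)
        )
    blocks.append(("KNF", pos, pos + len(knf_desc) - 1, tuple(knf_desc)))
    pos += len(knf_desc)

    ksnpf_desc = [
        f"{p[0]}{'X' * k}{p[1]}"
        for k in sorted(set(config.ksnpf_k))
        for p in DINUCLEOTIDES
    ]
    blocks.append(("KSNPF", pos, pos + len(ksnpf_desc) - 1, tuple(ksnpf_desc)))
    pos += len(ksnpf_desc)

    pse_desc = list(DINUCLEOTIDES) + [
        f"theta{j}" for j in range(1, config.psednc.lam + 1)
    ]
    blocks.append(("PseDNC", pos, pos + len(pse_desc) - 1, tuple(pse_desc)))

    return FeatureLayout(blocks=tuple(blocks))


@dataclass
class FeatureVector:
    """One encoded sample: ordered values plus the describing layout."""

    values: np.ndarray
    layout: FeatureLayout
    sample_id: str

    def __len__(self) -> int:
        return len(self.values)

    def block(self, family: str) -> np.ndarray:
        start, end = self.layout.block_range(family)
        return self.values[start - 1 : end]


def encode_all(
    sample: DnaSample, config: Optional[EncoderConfig] = None
) -> FeatureVector:
    """Assemble OHB + SNF + KNF + KSNPF + PseDNC for one sample."""
    if config is None:
        config = EncoderConfig()
    values = np.concatenate(
        [
            encode_ohb(sample),
            encode_snf(sample),
            encode_knf(sample, config.knf_k),
            encode_ksnpf(sample, config.ksnpf_k),
            encode_psednc(sample, config.psednc),
        ]
    )
    layout = build_layout(len(sample.sequence), config)
    return FeatureVector(values=values, layout=layout, sample_id=sample.id)


def encode_samples(
    samples: SampleSet, config: Optional[EncoderConfig] = None
) -> pd.DataFrame:
    """Encode a sample set into a feature table.

    Returns a frame with columns ``id``, ``label`` (NaN when unlabeled)
    and D1..Dn.
    """
    if config is None:
        config = EncoderConfig()
    layout = build_layout(samples.window_length, config)
    rows = np.empty((len(samples), layout.total_dim))
    for i, sample in enumerate(samples):
        rows[i] = encode_all(sample, config).values
    frame = pd.DataFrame(rows, columns=layout.dimension_names())
    frame.insert(0, "label", [s.label for s in samples])
    frame.insert(0, "id", samples.ids)
    return frame


def write_features(
    frame: pd.DataFrame, path: str | Path, layout: Optional[FeatureLayout] = None
) -> None:
    """Write a feature table as TSV; with a layout, also write a sidecar
    ``<path>.layout.tsv`` mapping dimension -> family/descriptor."""
    frame.to_csv(path, sep="\t", index=False)
    if layout is not None:
        layout.to_frame().to_csv(
            str(path) + ".layout.tsv", sep="\t", index=False
        )


def read_features(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    if "id" not in frame.columns or "label" not in frame.columns:
        raise ConfigurationError(
            f"{path}: feature table must have 'id' and 'label' columns"
        )
    return frame


def feature_matrix(frame: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Split a feature table into (X, y, ids); y entries are -1 if unlabeled."""
    dims = [c for c in frame.columns if c.startswith("D")]
    X = frame[dims].to_numpy(dtype=float)
    labels = frame["label"].to_numpy()
    y = np.where(pd.isna(labels), -1, labels).astype(int)
    return X, y, list(frame["id"].astype(str))
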