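import numpy as np
import pytest

from meth4c import default_motif, generate, generate_feature_table


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def write_fasta_file(tmp_path):
    """Return a helper writing (id, sequence) pairs to a FASTA file."""

    def _write(records, name="test.fa"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rec_id, seq in records:
                fh.write(f">{rec_id}\n{seq}\n")
        return path

    return _write


def random_window(rng, length=41, center_c=True):
    seq = list(rng.choice(list("ACGT"), size=length))
    if center_c:
        seq[length // 2] = "C"
    return "".join(seq)


@pytest.fixture
def small_windows(rng):
    """Six labeled 41-nt centre-C windows (3 positive, 3 negative)."""
    return generate(3, 3, default_motif(41, 1.0), seed=7)


@pytest.fixture
def separable_table():
    """Feature table where dimension 0 alone separates the classes."""
    X, y = generate_feature_table(80, 1, 9, effect=8.0, seed=11)
    return X, y
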