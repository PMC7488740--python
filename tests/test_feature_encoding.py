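import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meth4c.feature_encoding import (
    DINUCLEOTIDES,
    EncoderConfig,
    PseDncParams,
    build_layout,
    encode_all,
    encode_knf,
    encode_ksnpf,
    encode_ohb,
    encode_psednc,
    encode_samples,
    encode_snf,
    feature_matrix,
    load_property_table,
    read_features,
    write_features,
)
from meth4c.sequence_io import ConfigurationError, DnaSample
from meth4c.synthetic_data import default_motif, generate

dna = st.text(alphabet="ACGT", min_size=10, max_size=60)


# -- independent brute-force oracles ---------------------------------------

def oracle_knf(seq, k):
    kmers = ["".join(p) for p in itertools.product("ACGT", repeat=k)]
    return np.array(
        [
            sum(seq[i : i + k] == m for i in range(len(seq) - k + 1))
            / (len(seq) - k + 1)
            for m in kmers
        ]
    )


def oracle_ksnpf(seq, k):
    out = []
    for a, b in itertools.product("ACGT", repeat=2):
        count = sum(
            seq[i] == a and seq[i + k + 1] == b
            for i in range(len(seq) - k - 1)
        )
        out.append(count / (len(seq) - k - 1))
    return np.array(out)


class TestOhb:
    def test_quoted_per_nucleotide_codes(self):
        np.testing.assert_array_equal(encode_ohb("A")[:4], [1, 0, 0, 0])
        np.testing.assert_array_equal(encode_ohb("G")[:4], [0, 1, 0, 0])
        np.testing.assert_array_equal(encode_ohb("T")[:4], [0, 0, 1, 0])
        np.testing.assert_array_equal(encode_ohb("C")[:4], [0, 0, 0, 1])

    def test_41nt_window_gives_164_bits(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=41))
        assert len(encode_ohb(seq)) == 164

    def test_cg_hand_derived(self):
        np.testing.assert_array_equal(
            encode_ohb("CG"), [0, 0, 0, 1, 0, 1, 0, 0]
        )

    @given(dna)
    def test_one_hot_per_position(self, seq):
        v = encode_ohb(seq).reshape(-1, 4)
        assert np.all(v.sum(axis=1) == 1)
        assert set(np.unique(v)) <= {0.0, 1.0}


class TestSnf:
    def test_worked_example(self):
        # printed vector (1, 0.5, 0.33, 0.25, 0.2, 0.5, 0.28, 0.25);
        # position 2 is a typo in the source (the second A has density 1)
        got = encode_snf("AACGTACT")
        expected = [1, 1, 1 / 3, 1 / 4, 1 / 5, 3 / 6, 2 / 7, 2 / 8]
        np.testing.assert_allclose(got, expected)

    def test_first_entry_is_one(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=30))
        assert encode_snf(seq)[0] == 1.0

    def test_homopolymer_constant(self):
        np.testing.assert_array_equal(encode_snf("AAAA"), [1, 1, 1, 1])

    @given(dna)
    def test_bounds(self, seq):
        v = encode_snf(seq)
        i = np.arange(1, len(seq) + 1)
        assert np.all(v <= 1.0)
        assert np.all(v >= 1.0 / i)


class TestKnf:
    def test_homopolymer_k1(self):
        np.testing.assert_array_equal(
            encode_knf("AAAA", [1]), [1, 0, 0, 0]
        )

    def test_aacca_k2_hand_enumerated(self):
        got = encode_knf("AACCA", [2])
        expected = np.zeros(16)
        for mer in ("AA", "AC", "CC", "CA"):
            expected[DINUCLEOTIDES.index(mer)] = 0.25
        np.testing.assert_allclose(got, expected)

    def test_default_kset_length_20(self):
        assert len(encode_knf("ACGT" * 11)) == 20

    def test_k_too_large_rejected(self):
        with pytest.raises(ConfigurationError):
            encode_knf("ACGT", [5])

    @given(dna)
    @settings(max_examples=50)
    def test_blocks_sum_to_one(self, seq):
        v = encode_knf(seq, [1, 2])
        assert v[:4].sum() == pytest.approx(1.0)
        assert v[4:].sum() == pytest.approx(1.0)


class TestKsnpf:
    def test_acgt_k1_hand_enumerated(self):
        # pairs at distance 2: (A,G) and (C,T); denominator 4-1-1 = 2
        got = encode_ksnpf("ACGT", [1])
        expected = np.zeros(16)
        expected[DINUCLEOTIDES.index("AG")] = 0.5
        expected[DINUCLEOTIDES.index("CT")] = 0.5
        np.testing.assert_allclose(got, expected)

    def test_homopolymer(self):
        got = encode_ksnpf("AAAA", [1])
        assert got[DINUCLEOTIDES.index("AA")] == 1.0
        assert got.sum() == 1.0

    def test_default_kset_length_48(self):
        assert len(encode_ksnpf("ACGT" * 11)) == 48

    def test_k_too_large_rejected(self):
        with pytest.raises(ConfigurationError):
            encode_ksnpf("ACGTA", [4])

    @given(dna)
    @settings(max_examples=50)
    def test_blocks_sum_to_one(self, seq):
        v = encode_ksnpf(seq, [1, 2, 3]).reshape(3, 16)
        np.testing.assert_allclose(v.sum(axis=1), 1.0)


class TestOracleEquivalence:
    def test_knf_and_ksnpf_match_bruteforce_1000_random(self, rng):
        for _ in range(1000):
            length = int(rng.integers(10, 61))
            seq = "".join(rng.choice(list("ACGT"), size=length))
            for k in (1, 2):
                np.testing.assert_allclose(
                    encode_knf(seq, [k]), oracle_knf(seq, k)
                )
            for k in (1, 2, 3):
                np.testing.assert_allclose(
                    encode_ksnpf(seq, [k]), oracle_ksnpf(seq, k)
                )


class TestPseDnc:
    def test_degenerate_table_gives_zero_tail(self):
        table = pd.DataFrame(
            np.zeros((5, 16)), columns=DINUCLEOTIDES
        )
        params = PseDncParams(lam=3, property_table=table)
        v = encode_psednc("ACGTACGTAC", params)
        np.testing.assert_allclose(v[16:], 0.0)
        counts = np.zeros(16)
        for i in range(9):
            counts[DINUCLEOTIDES.index("ACGTACGTAC"[i : i + 2])] += 1
        np.testing.assert_allclose(v[:16], counts / counts.sum())

    def test_length_is_16_plus_lambda(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=41))
        assert len(encode_psednc(seq)) == 19

    def test_sums_to_one_100_random_cases(self, rng):
        for _ in range(100):
            length = int(rng.integers(10, 61))
            seq = "".join(rng.choice(list("ACGT"), size=length))
            raw = rng.normal(size=(38, 16))
            table = pd.DataFrame(
                (raw - raw.mean(1, keepdims=True)) / raw.std(1, keepdims=True),
                columns=DINUCLEOTIDES,
            )
            params = PseDncParams(
                lam=int(rng.integers(1, 6)), property_table=table
            )
            v = encode_psednc(seq, params)
            assert v.sum() == pytest.approx(1.0)
            assert np.all(v >= 0)

    def test_lambda_geq_length_rejected(self):
        with pytest.raises(ConfigurationError):
            encode_psednc("ACGTA", PseDncParams(lam=5))

    def test_default_property_table_standardized(self):
        table = load_property_table()
        assert table.shape == (38, 16)
        values = table.to_numpy()
        np.testing.assert_allclose(values.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(values.std(axis=1), 1.0, atol=1e-12)


class TestEncodeAll:
    def test_total_dim_292(self, small_windows):
        fv = encode_all(small_windows[0])
        assert len(fv) == 292

    def test_published_block_boundaries(self, small_windows):
        layout = encode_all(small_windows[0]).layout
        assert layout.block_range("OHB") == (1, 164)
        assert layout.block_range("SNF") == (165, 205)
        assert layout.block_range("KNF") == (206, 225)
        assert layout.block_range("KSNPF") == (226, 273)
        assert layout.block_range("PseDNC") == (274, 292)
        assert layout.total_dim == 292

    def test_block_value_ranges(self, small_windows):
        fv = encode_all(small_windows[0])
        assert set(np.unique(fv.block("OHB"))) <= {0.0, 1.0}
        snf = fv.block("SNF")
        assert np.all((snf > 0) & (snf <= 1))
        assert np.all((fv.block("KNF") >= 0) & (fv.block("KNF") <= 1))
        assert np.all((fv.block("KSNPF") >= 0) & (fv.block("KSNPF") <= 1))
        assert fv.block("PseDNC").sum() == pytest.approx(1.0)

    def test_deterministic(self, small_windows):
        a = encode_all(small_windows[0]).values
        b = encode_all(small_windows[0]).values
        np.testing.assert_array_equal(a, b)

    def test_shuffle_preserves_knf1_not_ohb(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=41))
        shuffled = "".join(rng.permutation(list(seq)))
        assert shuffled != seq  # overwhelmingly likely for this seed
        np.testing.assert_allclose(
            encode_knf(seq, [1]), encode_knf(shuffled, [1])
        )
        assert not np.array_equal(encode_ohb(seq), encode_ohb(shuffled))


class TestFeatureTableIO:
    def test_roundtrip_and_matrix(self, tmp_path, small_windows):
        config = EncoderConfig()
        frame = encode_samples(small_windows, config)
        assert frame.shape == (6, 294)  # id + label + 292 dims
        path = tmp_path / "features.tsv"
        write_features(frame, path, build_layout(41, config))
        back = read_features(path)
        X, y, ids = feature_matrix(back)
        assert X.shape == (6, 292)
        np.testing.assert_allclose(
            X, frame.iloc[:, 2:].to_numpy(), atol=1e-12
        )
        assert list(y) == [1, 1, 1, 0, 0, 0]
        assert ids == small_windows.ids
        layout_frame = pd.read_csv(
            str(path) + ".layout.tsv", sep="\t"
        )
        assert len(layout_frame) == 292
        assert layout_frame["family"].value_counts()["OHB"] == 164
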