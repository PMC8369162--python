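from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import aophmm
from aophmm import (
    AMINO_ACIDS,
    EncodingError,
    FeatureTable,
    ProteinSequence,
    aac,
    acc,
    dpc,
    encode_dataset,
    one_hot_matrix,
)
from aophmm.features import PositionMatrix, acc_names


def brute_force_dpc(m):
    """Naive double loop over positions and residue pairs."""
    L = m.shape[0]
    out = np.zeros((20, 20))
    for i in range(20):
        for j in range(20):
            for k in range(L - 1):
                out[i, j] += m[k, i] * m[k + 1, j]
    return out.ravel() / (L - 1)


def brute_force_acc(m, G):
    """Naive triple loop over lag, column pair, and position."""
    L = m.shape[0]
    means = m.mean(axis=0)
    out = []
    for g in range(1, G + 1):
        for j in range(20):
            for k in range(20):
                s = 0.0
                for i in range(L - g):
                    s += (m[i, j] - means[j]) * (m[i + g, k] - means[k])
                out.append(s / (L - g))
    return np.array(out)


class TestOneHot:
    def test_definition_on_short_sequence(self):
        m = one_hot_matrix(ProteinSequence("p", "AC")).values
        expected = np.zeros((2, 20))
        expected[0, 0] = 1.0  # A
        expected[1, 1] = 1.0  # C
        np.testing.assert_array_equal(m, expected)

    def test_rows_sum_to_one(self):
        m = one_hot_matrix(ProteinSequence("p", "ACDEFGHIKLMNPQRSTVWY")).values
        np.testing.assert_array_equal(m.sum(axis=1), np.ones(20))

    def test_single_residue_boundary(self):
        m = one_hot_matrix(ProteinSequence("p", "W")).values
        assert m.shape == (1, 20)
        assert m[0, AMINO_ACIDS.index("W")] == 1.0


class TestAac:
    def test_homopolymer(self):
        fv = aac(one_hot_matrix(ProteinSequence("p", "AAAA")))
        assert fv.values[0] == 1.0
        assert fv.values[1:].sum() == 0.0

    def test_uniform_composition(self):
        fv = aac(one_hot_matrix(ProteinSequence("p", "ACDE")))
        np.testing.assert_allclose(fv.values[:4], 0.25)

    def test_constant_hmm_matrix(self):
        m = PositionMatrix(values=np.full((7, 20), 0.05), source="hmm")
        np.testing.assert_allclose(aac(m).values, 0.05)

    def test_matches_string_counting(self, rng):
        residues = "".join(rng.choice(list(AMINO_ACIDS), size=60))
        fv = aac(one_hot_matrix(ProteinSequence("p", residues)))
        counts = Counter(residues)
        expected = np.array([counts[a] / 60 for a in AMINO_ACIDS])
        np.testing.assert_allclose(fv.values, expected)


class TestDpc:
    def test_homopolymer_single_pair(self):
        fv = dpc(one_hot_matrix(ProteinSequence("p", "AAAA")))
        assert fv.values[0] == 1.0  # (A, A)
        assert fv.values[1:].sum() == 0.0

    def test_one_hot_components_sum_to_one(self, rng):
        residues = "".join(rng.choice(list(AMINO_ACIDS), size=40))
        fv = dpc(one_hot_matrix(ProteinSequence("p", residues)))
        assert fv.values.sum() == pytest.approx(1.0)

    def test_matches_string_pair_counting(self, rng):
        residues = "".join(rng.choice(list(AMINO_ACIDS), size=50))
        fv = dpc(one_hot_matrix(ProteinSequence("p", residues)))
        pairs = Counter(zip(residues, residues[1:]))
        expected = np.array(
            [pairs[(a, b)] / 49 for a in AMINO_ACIDS for b in AMINO_ACIDS]
        )
        np.testing.assert_allclose(fv.values, expected)

    def test_matches_brute_force_on_hmm_matrix(self, rng):
        m = rng.uniform(0, 1, size=(6, 20))
        fv = dpc(PositionMatrix(values=m, source="hmm"))
        np.testing.assert_allclose(fv.values, brute_force_dpc(m), atol=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(EncodingError, match="too short"):
            dpc(one_hot_matrix(ProteinSequence("p", "A")))


class TestAcc:
    def test_matches_brute_force(self, rng):
        m = rng.uniform(0, 1, size=(12, 20))
        fv = acc(PositionMatrix(values=m, source="hmm"), G=3)
        np.testing.assert_allclose(fv.values, brute_force_acc(m, 3), atol=1e-12)

    def test_constant_column_contributes_zero(self, rng):
        m = rng.uniform(0, 1, size=(15, 20))
        m[:, 4] = 0.3
        fv = acc(PositionMatrix(values=m, source="hmm"), G=2)
        vals = fv.values.reshape(2, 20, 20)
        np.testing.assert_allclose(vals[:, 4, :], 0.0, atol=1e-15)
        np.testing.assert_allclose(vals[:, :, 4], 0.0, atol=1e-15)

    def test_shift_invariance(self, rng):
        m = rng.uniform(0, 0.5, size=(15, 20))
        shifted = m.copy()
        shifted[:, 7] += 0.4
        a = acc(PositionMatrix(values=m, source="hmm"), G=3).values
        b = acc(PositionMatrix(values=shifted, source="hmm"), G=3).values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_quadratic_scaling(self, rng):
        m = rng.uniform(0, 0.4, size=(18, 20))
        c = 2.5
        a = acc(PositionMatrix(values=m, source="hmm"), G=2).values
        b = acc(PositionMatrix(values=np.clip(c * m, 0, 1), source="hmm"), G=2).values
        np.testing.assert_allclose(b, c**2 * a, rtol=1e-10)

    def test_g10_yields_4000_components(self, rng):
        m = rng.uniform(0, 1, size=(30, 20))
        fv = acc(PositionMatrix(values=m, source="hmm"), G=10)
        assert len(fv.values) == 4000
        assert len(fv.names) == 4000

    @pytest.mark.parametrize("G,L", [(0, 10), (10, 10), (15, 10)])
    def test_invalid_lag_bound_rejected(self, rng, G, L):
        m = rng.uniform(0, 1, size=(L, 20))
        with pytest.raises(EncodingError, match=f"L={L}"):
            acc(PositionMatrix(values=m, source="hmm"), G=G)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        L=st.integers(min_value=5, max_value=30),
        G=st.integers(min_value=1, max_value=4),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    def test_brute_force_equivalence_property(self, L, G, seed):
        rng = np.random.default_rng(seed)
        m = rng.uniform(0, 1, size=(L, 20))
        fv = acc(PositionMatrix(values=m, source="hmm"), G=G)
        np.testing.assert_allclose(fv.values, brute_force_acc(m, G), atol=1e-12)


class TestRegistry:
    def test_names_unique_and_stable(self):
        names = acc_names(3)
        assert len(names) == len(set(names)) == 1200
        assert names == acc_names(3)
        # lag slowest, then j, then k
        assert names[0] == "ACC:j=A,k=A,g=1"
        assert names[400] == "ACC:j=A,k=A,g=2"
        assert names[1] == "ACC:j=A,k=C,g=1"
        assert names[20] == "ACC:j=C,k=A,g=1"


class TestEncodeDataset:
    def test_acc_table_shape(self, rng):
        profs = [
            aophmm.HMMProfile(id=f"p{i}", matrix=rng.uniform(0, 1, size=(25, 20)))
            for i in range(3)
        ]
        t = encode_dataset(profs, ["AOP", "non-AOP", "AOP"], scheme="acc", G=10)
        assert t.X.shape == (3, 4000)

    def test_seq_aac_table_shape(self):
        seqs = [ProteinSequence("a", "ACDE"), ProteinSequence("b", "WYWY")]
        t = encode_dataset(seqs, ["AOP", "non-AOP"], scheme="seq-aac")
        assert t.X.shape == (2, 20)

    def test_precondition_failure_names_offender(self, rng):
        profs = [
            aophmm.HMMProfile(id="ok", matrix=rng.uniform(0, 1, size=(25, 20))),
            aophmm.HMMProfile(id="shorty", matrix=rng.uniform(0, 1, size=(5, 20))),
        ]
        with pytest.raises(EncodingError, match="shorty"):
            encode_dataset(profs, ["AOP", "non-AOP"], scheme="acc", G=10)

    def test_row_order_matches_input_order(self, rng):
        profs = [
            aophmm.HMMProfile(id=f"p{i}", matrix=rng.uniform(0, 1, size=(10, 20)))
            for i in range(4)
        ]
        t = encode_dataset(profs, ["AOP"] * 4, scheme="hmm-aac")
        assert t.ids == [f"p{i}" for i in range(4)]

    def test_tsv_roundtrip(self, tmp_path, small_two_class_table):
        path = tmp_path / "t.tsv"
        small_two_class_table.to_tsv(path)
        back = FeatureTable.from_tsv(path)
        np.testing.assert_allclose(back.X, small_two_class_table.X, atol=1e-9)
        assert back.names == small_two_class_table.names
        assert back.ids == small_two_class_table.ids
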