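"""Residue codes, pseudo-PSSM, normalization, augmentation, PSSM-400,
and hashed n-gram embeddings."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from snarefuse.encoding import (
    EmbeddingConfig,
    augment_pssm,
    blosum62_table,
    compute_pseudo_pssm,
    embed_ngrams,
    encode_residues,
    init_embedding_table,
    ngram_hash,
    ngram_ids,
    normalize_pssm,
    pssm_to_400,
    EncodedSequence,
)
from snarefuse.sequence_io import CANONICAL_ORDER, ProteinSequence, PSSMatrix

residue_strings = st.text(alphabet=CANONICAL_ORDER + "X", min_size=1,
                          max_size=40)


def make_pssm(values, seq_id="s"):
    return PSSMatrix(sequence_id=seq_id, scores=np.asarray(values, float))


class TestEncodeResidues:
    @pytest.mark.parametrize("residues,expected", [
        ("A", [0]),
        ("ARNDV", [0, 1, 2, 3, 19]),
        ("MXM", [12, 20, 12]),
    ])
    def test_canonical_codes(self, residues, expected):
        enc = encode_residues(ProteinSequence("s", residues))
        assert enc.codes.tolist() == expected

    @given(residue_strings)
    def test_codes_decode_back(self, s):
        alphabet = CANONICAL_ORDER + "X"
        enc = encode_residues(ProteinSequence("s", s))
        assert "".join(alphabet[c] for c in enc.codes) == s


class TestPseudoPssm:
    def test_one_hot_table(self):
        table = np.zeros((21, 20))
        table[:20] = np.eye(20)
        pssm = compute_pseudo_pssm(ProteinSequence("s", "AA"), table)
        assert pssm.scores.shape == (2, 20)
        np.testing.assert_array_equal(pssm.scores, np.eye(20)[[0, 0]])

    def test_mask_row_is_zero(self):
        table = np.zeros((21, 20))
        table[:20] = np.eye(20)
        pssm = compute_pseudo_pssm(ProteinSequence("s", "AX"), table)
        np.testing.assert_array_equal(pssm.scores[1], np.zeros(20))

    def test_blosum62_row_matches_published_values(self):
        # spot-checks of the published BLOSUM62 entries for the M row
        pssm = compute_pseudo_pssm(ProteinSequence("s", "MKV"))
        m_row = pssm.scores[0]
        assert m_row[CANONICAL_ORDER.index("M")] == 5    # M-M
        assert m_row[CANONICAL_ORDER.index("L")] == 2    # M-L
        assert m_row[CANONICAL_ORDER.index("A")] == -1   # M-A
        assert m_row[CANONICAL_ORDER.index("P")] == -2   # M-P
        k_row = pssm.scores[1]
        assert k_row[CANONICAL_ORDER.index("K")] == 5
        assert k_row[CANONICAL_ORDER.index("R")] == 2


class TestNormalizePssm:
    def test_logistic_values(self):
        row = np.array([[-2.0, 0.0, 2.0] + [0.0] * 17])
        out = normalize_pssm(make_pssm(row), "logistic").scores
        assert out[0, 0] == pytest.approx(1 / (1 + np.exp(2.0)), abs=1e-12)
        assert out[0, 1] == pytest.approx(0.5, abs=1e-15)
        assert out[0, 2] == pytest.approx(1 / (1 + np.exp(-2.0)), abs=1e-12)

    def test_constant_matrix_length_scaled_is_half(self):
        out = normalize_pssm(make_pssm(np.full((4, 20), 3.0)),
                             "length_scaled").scores
        np.testing.assert_array_equal(out, np.full((4, 20), 0.5))

    @pytest.mark.parametrize("mode", ["logistic", "length_scaled"])
    def test_bounded_and_monotone(self, mode):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 5, size=(6, 20))
        b = a + rng.uniform(0, 2, size=a.shape)  # b >= a entrywise
        na = normalize_pssm(make_pssm(a), mode).scores
        nb = normalize_pssm(make_pssm(b), mode).scores
        for m in (na, nb):
            assert m.min() >= 0.0 and m.max() <= 1.0
        if mode == "logistic":
            assert np.all(nb >= na)
        else:
            # same affine map applies to both only within one matrix; check
            # monotonicity within a single matrix via sorting order
            flat = a.ravel()
            nflat = na.ravel()
            order = np.argsort(flat)
            assert np.all(np.diff(nflat[order]) >= -1e-12)


class TestAugmentPssm:
    def test_single_row_blocks_equal(self):
        aug = augment_pssm(make_pssm(np.arange(20)[None]))
        np.testing.assert_array_equal(aug.left, aug.right)

    def test_right_block_is_row_reversed(self):
        rows = np.arange(60).reshape(3, 20)
        aug = augment_pssm(make_pssm(rows))
        np.testing.assert_array_equal(aug.left, rows)
        np.testing.assert_array_equal(aug.right, rows[::-1])

    def test_reversal_is_involution(self):
        rows = np.random.default_rng(1).normal(size=(5, 20))
        aug = augment_pssm(make_pssm(rows))
        back = augment_pssm(make_pssm(aug.right))
        np.testing.assert_array_equal(back.right, rows)

    def test_value_multiset_preserved(self):
        rows = np.random.default_rng(2).normal(size=(4, 20))
        aug = augment_pssm(make_pssm(rows))
        assert sorted(aug.combined.ravel()) == \
            sorted(np.concatenate([rows, rows]).ravel())


class TestPssmTo400:
    def test_homogeneous_sequence(self):
        seq = encode_residues(ProteinSequence("s", "AAAA"))
        vec = pssm_to_400(seq, make_pssm(np.ones((4, 20))))
        expected = np.zeros(400)
        expected[:20] = 1.0
        np.testing.assert_allclose(vec, expected)

    def test_two_residue_split(self):
        seq = encode_residues(ProteinSequence("s", "AR"))
        vec = pssm_to_400(seq, make_pssm(np.ones((2, 20)))).reshape(20, 20)
        np.testing.assert_allclose(vec[0], 0.5)
        np.testing.assert_allclose(vec[1], 0.5)
        assert np.all(vec[2:] == 0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            m = int(rng.integers(3, 12))
            codes = rng.integers(0, 21, size=m)
            seq = EncodedSequence(codes)
            scores = rng.uniform(0, 1, size=(m, 20))
            vec = pssm_to_400(seq, make_pssm(scores))
            oracle = np.zeros((20, 20))
            for i in range(m):
                if codes[i] < 20:
                    for b in range(20):
                        oracle[codes[i], b] += scores[i, b]
            np.testing.assert_allclose(vec, (oracle / m).ravel(), atol=1e-12)

    def test_linearity_and_conservation(self):
        rng = np.random.default_rng(10)
        m = 8
        codes = rng.integers(0, 21, size=m)
        seq = EncodedSequence(codes)
        scores = rng.uniform(0, 1, size=(m, 20))
        vec = pssm_to_400(seq, make_pssm(scores))
        np.testing.assert_allclose(
            pssm_to_400(seq, make_pssm(0.5 * scores)), 0.5 * vec, atol=1e-13)
        used = scores[codes < 20].sum()
        assert vec.sum() == pytest.approx(used / m, rel=1e-12)

    def test_length_mismatch_rejected(self):
        seq = encode_residues(ProteinSequence("s", "ARN"))
        with pytest.raises(ValueError):
            pssm_to_400(seq, make_pssm(np.ones((4, 20))))


class TestNgramEmbedding:
    def test_unigram_only_returns_table_row(self):
        cfg = EmbeddingConfig(ngram_orders=frozenset({1}), embedding_dim=4,
                              hash_buckets=16)
        table = np.random.default_rng(0).normal(size=(16, 4))
        seq = ProteinSequence("s", "AR")
        out = embed_ngrams(seq, cfg, table)
        np.testing.assert_array_equal(out[0], table[ngram_hash("A", 16)])
        np.testing.assert_array_equal(out[1], table[ngram_hash("R", 16)])

    def test_deterministic_across_calls(self):
        cfg = EmbeddingConfig(embedding_dim=8, hash_buckets=64)
        table = init_embedding_table(cfg)
        seq = ProteinSequence("s", "MKVLL")
        np.testing.assert_array_equal(embed_ngrams(seq, cfg, table),
                                      embed_ngrams(seq, cfg, table))

    def test_position_vector_is_mean_of_hashed_rows(self):
        # independent recomputation of the FNV-1a hash and the mean
        cfg = EmbeddingConfig(ngram_orders=frozenset({1, 2}),
                              embedding_dim=5, hash_buckets=32)
        table = np.random.default_rng(1).normal(size=(32, 5))
        out = embed_ngrams(ProteinSequence("s", "ARN"), cfg, table)

        def fnv(s):
            h = 0xCBF29CE484222325
            for b in s.encode():
                h = ((h ^ b) * 0x100000001B3) & 0xFFFFFFFFFFFFFFFF
            return h % 32

        expected = (table[fnv("N")] + table[fnv("RN")]) / 2
        np.testing.assert_allclose(out[2], expected, atol=1e-14)

    def test_ids_mark_absent_ngrams(self):
        cfg = EmbeddingConfig(ngram_orders=frozenset({1, 3}),
                              embedding_dim=4, hash_buckets=8)
        ids = ngram_ids("ARN", cfg)
        assert ids.shape == (3, 2)
        assert ids[0, 1] == -1 and ids[1, 1] == -1 and ids[2, 1] >= 0
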