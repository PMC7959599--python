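from collections import Counter
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from promokit import (
    KmerVocabulary,
    SeqRecord,
    encode_dataset,
    fbt_encode,
    fit_vocabulary,
    kmerize,
    onehot_decode,
    onehot_encode,
)

seqs = st.text(alphabet="ACGT", min_size=1, max_size=60)


class TestKmerize:
    @pytest.mark.parametrize(
        "bases,k,expected",
        [
            ("ACGT", 2, ["AC", "CG", "GT"]),
            ("ACGT", 4, ["ACGT"]),
            ("ACGT", 1, list("ACGT")),
        ],
    )
    def test_window_enumeration(self, bases, k, expected):
        assert kmerize(bases, k) == expected

    def test_kmer_count_formula(self, rng):
        bases = "".join(rng.choice(list("ACGT"), size=1000))
        assert len(kmerize(bases, 8)) == 993

    def test_stride(self):
        assert kmerize("ACGTAC", 2, stride=2) == ["AC", "GT", "AC"]

    def test_errors(self):
        with pytest.raises(ValueError):
            kmerize("ACG", 4)
        with pytest.raises(ValueError):
            kmerize("ACGN", 2)

    @given(bases=seqs, k=st.integers(1, 8), stride=st.integers(1, 3))
    @settings(max_examples=100, deadline=None)
    def test_count_matches_closed_form(self, bases, k, stride):
        if k > len(bases):
            return
        got = kmerize(bases, k, stride)
        assert len(got) == (len(bases) - k) // stride + 1
        assert all(len(w) == k for w in got)


def brute_force_rank(corpus, k):
    """Independent oracle: count with Counter, sort by (-count, kmer)."""
    counts = Counter()
    for s in corpus:
        for i in range(len(s) - k + 1):
            counts[s[i : i + k]] += 1
    ordered = sorted(counts, key=lambda km: (-counts[km], km))
    return {km: i + 1 for i, km in enumerate(ordered)}, counts


class TestVocabulary:
    def test_hand_counted_example(self):
        v = fit_vocabulary(["AAC", "ACA"], 1)
        assert v.counts == {"A": 4, "C": 2}
        assert v.index_of == {"A": 1, "C": 2}

    def test_tie_broken_lexicographically(self):
        v = fit_vocabulary(["AC", "CA"], 1)
        assert v.index_of == {"A": 1, "C": 2}

    def test_empty_corpus_raises(self):
        with pytest.raises(ValueError):
            fit_vocabulary([], 2)

    def test_index_zero_never_assigned(self, rng):
        corpus = ["".join(rng.choice(list("ACGT"), size=50)) for _ in range(20)]
        v = fit_vocabulary(corpus, 2)
        assert 0 not in v.index_of.values()
        assert sorted(v.index_of.values()) == list(range(1, v.size + 1))

    @given(
        corpus=st.lists(st.text(alphabet="ACGT", min_size=4, max_size=30),
                        min_size=1, max_size=8),
        k=st.sampled_from([1, 2, 4]),
    )
    @settings(max_examples=100, deadline=None)
    def test_agrees_with_brute_force_ranking(self, corpus, k):
        v = fit_vocabulary(corpus, k)
        expected_idx, expected_counts = brute_force_rank(corpus, k)
        assert v.index_of == expected_idx
        assert v.counts == dict(expected_counts)

    def test_tsv_roundtrip(self, tmp_path):
        v = fit_vocabulary(["ACGTACGT", "TTGGAACC"], 2)
        path = tmp_path / "vocab.tsv"
        v.save(path)
        back = KmerVocabulary.load(path)
        assert back.k == v.k
        assert back.index_of == v.index_of
        assert back.checksum() == v.checksum()


class TestFBT:
    def test_direct_lookup(self):
        v = KmerVocabulary(k=1, index_of={"A": 1, "C": 2}, counts={"A": 4, "C": 2})
        assert fbt_encode("AAC", v).tokens.tolist() == [1, 1, 2]

    def test_oov_maps_to_zero(self):
        v = KmerVocabulary(k=1, index_of={"A": 1}, counts={"A": 3})
        assert fbt_encode("AGA", v).tokens.tolist() == [1, 0, 1]

    def test_training_corpus_never_contains_zero(self, rng):
        corpus = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(10)]
        v = fit_vocabulary(corpus, 2)
        for s in corpus:
            assert 0 not in fbt_encode(s, v).tokens

    def test_token_vector_length(self, rng):
        bases = "".join(rng.choice(list("ACGT"), size=1000))
        v = fit_vocabulary([bases], 2)
        assert len(fbt_encode(bases, v).tokens) == 999


class TestOneHot:
    def test_k1_indicator_columns(self):
        m = onehot_encode("AC", 1).matrix
        assert m[:, 0].tolist() == [1, 0, 0, 0]
        assert m[:, 1].tolist() == [0, 1, 0, 0]

    @pytest.mark.parametrize("k,shape", [(1, (4, 1000)), (2, (16, 999))])
    def test_shapes_for_1000nt(self, rng, k, shape):
        bases = "".join(rng.choice(list("ACGT"), size=1000))
        assert onehot_encode(bases, k).matrix.shape == shape

    def test_columns_sum_to_one(self, rng):
        bases = "".join(rng.choice(list("ACGT"), size=200))
        m = onehot_encode(bases, 4).matrix
        assert (m.sum(axis=0) == 1).all()

    def test_channel_order_lexicographic(self):
        m = onehot_encode("GG", 2)
        channels = m.channel_order
        assert channels == ["".join(p) for p in product("ACGT", repeat=2)]
        assert m.matrix[channels.index("GG"), 0] == 1

    def test_single_column_decode(self):
        mat = np.zeros((4, 1), dtype=np.uint8)
        mat[2, 0] = 1
        from promokit.encoding import OneHotMatrix

        assert onehot_decode(OneHotMatrix(matrix=mat, k=1)) == "G"

    def test_overlap_mismatch_detected(self):
        from promokit.encoding import OneHotMatrix

        a = onehot_encode("AC", 2).matrix
        b = onehot_encode("GG", 2).matrix
        bad = np.concatenate([a, b], axis=1)
        with pytest.raises(ValueError, match="mismatch"):
            onehot_decode(OneHotMatrix(matrix=bad, k=2))

    @given(bases=st.text(alphabet="ACGT", min_size=8, max_size=64),
           k=st.sampled_from([1, 2, 4, 8]))
    @settings(max_examples=100, deadline=None)
    def test_decode_inverts_encode(self, bases, k):
        assert onehot_decode(onehot_encode(bases, k)) == bases

    @given(bases=st.text(alphabet="ACGT", min_size=8, max_size=40),
           k=st.sampled_from([1, 2, 4]))
    @settings(max_examples=60, deadline=None)
    def test_fbt_and_onehot_lengths_agree(self, bases, k):
        v = fit_vocabulary([bases], k)
        assert (
            len(fbt_encode(bases, v).tokens)
            == onehot_encode(bases, k).matrix.shape[1]
            == len(bases) - k + 1
        )


class TestEncodeDataset:
    def test_fbt_dataset_shapes_and_checksum(self):
        recs = [SeqRecord("a", "ACGTACGT", label=1), SeqRecord("b", "TTGGCCAA", label=0)]
        v = fit_vocabulary([r.bases for r in recs], 2)
        data = encode_dataset(recs, "fbt", 2, vocab=v)
        assert data.X.shape == (2, 7)
        assert data.y.tolist() == [1, 0]
        assert data.vocab_checksum == v.checksum()

    def test_onehot_dataset_layout(self):
        recs = [SeqRecord("a", "ACGTACGT", label=1)]
        data = encode_dataset(recs, "onehot", 2)
        assert data.X.shape == (1, 7, 16)
        assert (data.X.sum(axis=2) == 1).all()

    def test_mixed_lengths_rejected(self):
        recs = [SeqRecord("a", "ACGT", label=1), SeqRecord("b", "ACGTA", label=0)]
        with pytest.raises(ValueError, match="mixed"):
            encode_dataset(recs, "onehot", 2)
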