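"""k-merization, frequency-based tokenization (FBT) and one-hot encoding.

A sequence of length L yields L - k + 1 overlapping k-mers at stride 1.
FBT maps each k-mer to an integer rank assigned by descending corpus
frequency, starting at 1; index 0 is reserved for out-of-vocabulary
k-mers (and padding), so a vocabulary fitted on a corpus never emits 0
on that corpus. One-hot encoding represents each k-mer as an indicator
column over all 4**k possible k-mers in lexicographic order (A < C < G < T),
giving a binary matrix of shape (4**k, L - k + 1) per sequence.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io import VALID_BASES, SeqRecord

__all__ = [
    "kmerize",
    "KmerVocabulary",
    "fit_vocabulary",
    "fbt_encode",
    "onehot_encode",
    "onehot_decode",
    "EncodedVector",
    "OneHotMatrix",
    "EncodedDataset",
    "encode_dataset",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"


def _check_acgt(bases: str) -> None:
    if not set(bases) <= VALID_BASES:
        bad = sorted(set(bases) - VALID_BASES)
        raise ValueError(f"sequence contains non-ACGT characters: {bad}")


def kmerize(bases: str, k: int, stride: int = 1) -> list[str]:
    """Overlapping k-mers of ``bases`` at the given stride.

    Returns ``floor((L - k) / stride) + 1`` windows for a length-L input.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if k < 1 or k > len(bases):
        raise ValueError(f"k={k} out of range for sequence of length {len(bases)}")
    _check_acgt(bases)
    return [bases[i : i + k] for i in range(0, len(bases) - k + 1, stride)]


def _token_codes(bases: str, k: int) -> np.ndarray:
    """Integer code in [0, 4**k) of each overlapping k-mer, vectorised."""
    arr = np.frombuffer(bases.encode("ascii"), dtype=np.uint8)
    lut = np.zeros(128, dtype=np.int64)
    for b, v in _BASE_INDEX.items():
        lut[ord(b)] = v
    digits = lut[arr]
    n = len(bases) - k + 1
    codes = np.zeros(n, dtype=np.int64)
    for j in range(k):
        codes = codes * 4 + digits[j : j + n]
    return codes


@dataclass
class KmerVocabulary:
    """Frequency-ranked k-mer vocabulary with reserved index 0.

    ``index_of`` maps each k-mer to a rank in 1..V assigned by descending
    corpus count, ties broken lexicographically ascending. Index 0 is never
    assigned; it marks out-of-vocabulary k-mers at encode time.
    """

    k: int
    index_of: dict[str, int]
    counts: dict[str, int]

    def __post_init__(self) -> None:
        idx = sorted(self.index_of.values())
        if idx != list(range(1, len(idx) + 1)):
            raise ValueError("vocabulary indices must be consecutive 1..V")

    @property
    def size(self) -> int:
        return len(self.index_of)

    def checksum(self) -> str:
        """Stable digest of (k, k-mer, index) content, for input contracts."""
        h = hashlib.sha256()
        h.update(f"k={self.k}\n".encode())
        for kmer, i in sorted(self.index_of.items()):
            h.update(f"{kmer}\t{i}\n".encode())
        return h.hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        """Two-column TSV (k-mer, index) with a header recording k and mass."""
        total = sum(self.counts.values())
        with open(path, "w") as fh:
            fh.write(f"# k={self.k}\ttotal_kmers={total}\n")
            for kmer, i in sorted(self.index_of.items(), key=lambda kv: kv[1]):
                fh.write(f"{kmer}\t{i}\t{self.counts.get(kmer, 0)}\n")

    @classmethod
    def load(cls, path: str | Path) -> "KmerVocabulary":
        index_of: dict[str, int] = {}
        counts: dict[str, int] = {}
        k = None
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    for tok in line[1:].split():
                        if tok.startswith("k="):
                            k = int(tok[2:])
                    continue
                kmer, idx, cnt = line.rstrip("\n").split("\t")
                index_of[kmer] = int(idx)
                counts[kmer] = int(cnt)
        if k is None:
            if not index_of:
                raise ValueError(f"empty vocabulary file: {path}")
            k = len(next(iter(index_of)))
        return cls(k=k, index_of=index_of, counts=counts)


def fit_vocabulary(corpus: Iterable[str], k: int) -> KmerVocabulary:
    """Fit a frequency-ranked vocabulary on a corpus of A/C/G/T strings.

    Counts aggregate over every overlapping k-mer of every sequence. Fit on
    the training split only: encoding held-out data with a frozen vocabulary
    maps unseen k-mers to the reserved index 0.
    """
    total = np.zeros(4**k, dtype=np.int64)
    n_seqs = 0
    for bases in corpus:
        if len(bases) < k:
            raise ValueError(
                f"corpus sequence of length {len(bases)} is shorter than k={k}"
            )
        _check_acgt(bases)
        total += np.bincount(_token_codes(bases, k), minlength=4**k)
        n_seqs += 1
    if n_seqs == 0:
        raise ValueError("cannot fit a vocabulary on an empty corpus")
    present = np.flatnonzero(total)
    # descending count; ties lexicographic ascending (code order is lexicographic)
    order = present[np.lexsort((present, -total[present]))]
    index_of: dict[str, int] = {}
    counts: dict[str, int] = {}
    for rank, code in enumerate(order, start=1):
        kmer = _code_to_kmer(int(code), k)
        index_of[kmer] = rank
        counts[kmer] = int(total[code])
    return KmerVocabulary(k=k, index_of=index_of, counts=counts)


def _code_to_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


@dataclass
class EncodedVector:
    """Integer token sequence of one FBT-encoded sequence."""

    tokens: np.ndarray
    k: int
    source_length: int

    def __post_init__(self) -> None:
        assert len(self.tokens) == self.source_length - self.k + 1


@dataclass
class OneHotMatrix:
    """Binary indicator matrix of shape (4**k, L - k + 1)."""

    matrix: np.ndarray
    k: int

    @property
    def channel_order(self) -> list[str]:
        return ["".join(p) for p in product(_BASES, repeat=self.k)]


def fbt_encode(bases: str, vocab: KmerVocabulary) -> EncodedVector:
    """Encode a sequence as frequency-rank tokens under a fitted vocabulary.

    Position i carries the rank of k-mer i, or 0 if that k-mer is absent
    from the vocabulary.
    """
    k = vocab.k
    if len(bases) < k:
        raise ValueError(f"sequence shorter than k={k}")
    _check_acgt(bases)
    codes = _token_codes(bases, k)
    lut = np.zeros(4**k, dtype=np.int64)
    for kmer, idx in vocab.index_of.items():
        lut[_kmer_to_code(kmer)] = idx
    return EncodedVector(tokens=lut[codes], k=k, source_length=len(bases))


def _kmer_to_code(kmer: str) -> int:
    code = 0
    for ch in kmer:
        code = code * 4 + _BASE_INDEX[ch]
    return code


def onehot_encode(bases: str, k: int) -> OneHotMatrix:
    """One-hot matrix of a sequence's overlapping k-mers.

    Channel c of column i is 1 iff k-mer i is the c-th k-mer in
    lexicographic order; every column sums to exactly 1.
    """
    if len(bases) < k:
        raise ValueError(f"sequence shorter than k={k}")
    _check_acgt(bases)
    codes = _token_codes(bases, k)
    mat = np.zeros((4**k, len(codes)), dtype=np.uint8)
    mat[codes, np.arange(len(codes))] = 1
    return OneHotMatrix(matrix=mat, k=k)


def onehot_decode(onehot: OneHotMatrix) -> str:
    """Reconstruct the source sequence from a one-hot k-mer matrix.

    Requires every column to be a valid indicator and consecutive windows
    to agree on their k-1 overlapping characters.
    """
    mat = np.asarray(onehot.matrix)
    k = onehot.k
    if mat.ndim != 2 or mat.shape[0] != 4**k:
        raise ValueError(f"matrix must have 4**k = {4**k} rows")
    colsums = mat.sum(axis=0)
    if not np.all(colsums == 1):
        raise ValueError("every column must contain exactly one 1")
    codes = mat.argmax(axis=0)
    kmers = [_code_to_kmer(int(c), k) for c in codes]
    for i in range(len(kmers) - 1):
        if kmers[i][1:] != kmers[i + 1][:-1]:
            raise ValueError(
                f"overlap mismatch between windows {i} ({kmers[i]}) and "
                f"{i + 1} ({kmers[i + 1]})"
            )
    return kmers[0] + "".join(km[-1] for km in kmers[1:])


@dataclass
class EncodedDataset:
    """A model-ready encoded corpus with its input contract.

    ``X`` is (n, L-k+1) int64 tokens for FBT, or (n, L-k+1, 4**k) uint8 for
    one-hot (positions-first so both encoders share the layout consumed by
    the 1D models). ``vocab_checksum`` is empty for one-hot.
    """

    X: np.ndarray
    y: np.ndarray
    encoder: str
    k: int
    source_length: int
    vocab_checksum: str = ""
    vocab_size: int = 0
    ids: list[str] = field(default_factory=list)

    @property
    def n_positions(self) -> int:
        return self.source_length - self.k + 1


def encode_dataset(
    records: Sequence[SeqRecord],
    encoder: str,
    k: int,
    vocab: KmerVocabulary | None = None,
) -> EncodedDataset:
    """Encode a labelled record list into a stacked array dataset.

    All records must share one length. ``encoder`` is ``"fbt"`` (requires a
    fitted vocabulary) or ``"onehot"``.
    """
    if not records:
        raise ValueError("no records to encode")
    lengths = {len(r.bases) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"records have mixed lengths: {sorted(lengths)}")
    L = lengths.pop()
    y = np.array(
        [r.label if r.label is not None else -1 for r in records], dtype=np.int64
    )
    ids = [r.id for r in records]
    if encoder == "fbt":
        if vocab is None:
            raise ValueError("FBT encoding requires a fitted vocabulary")
        if vocab.k != k:
            raise ValueError(f"vocabulary k={vocab.k} does not match k={k}")
        X = np.stack([fbt_encode(r.bases, vocab).tokens for r in records])
        return EncodedDataset(
            X=X, y=y, encoder="fbt", k=k, source_length=L,
            vocab_checksum=vocab.checksum(), vocab_size=vocab.size, ids=ids,
        )
    if encoder == "onehot":
        # positions-first layout: (n, L-k+1, 4**k)
        X = np.stack([onehot_encode(r.bases, k).matrix.T for r in records])
        return EncodedDataset(
            X=X, y=y, encoder="onehot", k=k, source_length=L,
            vocab_size=4**k, ids=ids,
        )
    raise ValueError(f"unknown encoder {encoder!r} (use 'fbt' or 'onehot')")
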