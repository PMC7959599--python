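"""Synthetic negative (background) sets by shuffling promoter sequences.

Shuffling a promoter preserves its base composition while destroying any
positional signal, which makes the negative class composition-matched and
forces a classifier to learn sequence structure rather than GC content.
Two modes:

* ``mononucleotide`` — a uniform random permutation of the characters;
  preserves single-nucleotide counts.
* ``dinucleotide`` — a random Eulerian walk on the dinucleotide transition
  multigraph (Altschul–Erickson style); preserves all 16 dinucleotide
  counts and the first and last character exactly.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .io import SeqRecord

__all__ = ["SHUFFLE_MODES", "shuffle_sequence", "build_binary_dataset"]

SHUFFLE_MODES = ("mononucleotide", "dinucleotide")


def shuffle_sequence(bases: str, mode: str = "mononucleotide", seed: int = 0) -> str:
    """Return a composition-preserving shuffle of ``bases``.

    Deterministic under ``seed``. Mononucleotide mode needs length >= 2,
    dinucleotide mode length >= 3.
    """
    if mode not in SHUFFLE_MODES:
        raise ValueError(f"mode must be one of {SHUFFLE_MODES}, got {mode!r}")
    rng = np.random.default_rng(seed)
    if mode == "mononucleotide":
        if len(bases) < 2:
            raise ValueError("mononucleotide shuffle needs length >= 2")
        arr = np.frombuffer(bases.encode("ascii"), dtype=np.uint8).copy()
        rng.shuffle(arr)
        return arr.tobytes().decode("ascii")
    if len(bases) < 3:
        raise ValueError("dinucleotide shuffle needs length >= 3")
    return _dinucleotide_shuffle(bases, rng)


def _dinucleotide_shuffle(bases: str, rng: np.random.Generator) -> str:
    """Random Eulerian path through the dinucleotide multigraph.

    Every adjacent pair (edge) of the input is used exactly once, so all 16
    dinucleotide counts — and hence also the mononucleotide counts and the
    terminal characters — are conserved.
    """
    first, last = bases[0], bases[-1]
    # adjacency: multiset of successors per vertex
    succ: dict[str, list[str]] = {}
    for a, b in zip(bases, bases[1:]):
        succ.setdefault(a, []).append(b)
    vertices = sorted(succ)
    if len(vertices) == 1:
        return bases  # single repeated transition source, walk is forced

    # Choose each non-terminal vertex's final outgoing edge so the chosen
    # edges form a tree pointing to `last`; rejection-sample until connected.
    non_last = [v for v in vertices if v != last]
    while True:
        last_edge = {
            v: succ[v][int(rng.integers(len(succ[v])))] for v in non_last
        }
        ok = True
        for v in non_last:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break

    # Shuffle the remaining edges per vertex; append the reserved last edge.
    walk_lists: dict[str, list[str]] = {}
    for v in vertices:
        edges = list(succ[v])
        if v in last_edge:
            edges.remove(last_edge[v])
        perm = rng.permutation(len(edges))
        ordered = [edges[i] for i in perm]
        if v in last_edge:
            ordered.append(last_edge[v])
        walk_lists[v] = ordered

    out = [first]
    pos = {v: 0 for v in vertices}
    cur = first
    for _ in range(len(bases) - 1):
        nxt = walk_lists[cur][pos[cur]]
        pos[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def build_binary_dataset(
    promoters: Sequence[SeqRecord],
    mode: str = "mononucleotide",
    seed: int = 0,
) -> list[SeqRecord]:
    """Pair every promoter with one shuffled negative; 1:1 by construction.

    Returns 2n records: the n promoters labelled 1 followed by their
    shuffled counterparts labelled 0 (id suffixed ``_shuf``). Each negative
    gets an independent per-record seed derived from the master seed and
    the record index, so the result is order-independent and reproducible.
    """
    if not promoters:
        raise ValueError("cannot build a dataset from an empty promoter list")
    seeds = np.random.SeedSequence(seed).generate_state(len(promoters))
    positives, negatives = [], []
    for i, rec in enumerate(promoters):
        positives.append(
            SeqRecord(id=rec.id, bases=rec.bases, species=rec.species, label=1)
        )
        shuf = shuffle_sequence(rec.bases, mode=mode, seed=int(seeds[i]))
        negatives.append(
            SeqRecord(
                id=f"{rec.id}_shuf", bases=shuf, species=rec.species, label=0
            )
        )
    return positives + negatives
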