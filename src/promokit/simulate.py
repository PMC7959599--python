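"""Synthetic promoter-like corpora with planted positional motifs.

Real promoters carry positional sequence elements (TATA box, CAAT box,
GC box) at roughly fixed offsets from the transcription start site, over a
species-specific background composition. The generator emulates exactly
that structure: i.i.d. A/C/G/T background at a controllable GC fraction,
with short motifs written at fixed offsets and corrupted by a per-position
mutation probability. Three default pseudo-species profiles carry
pairwise-distinct motifs and backgrounds, so that within-species
classification is learnable and cross-species transfer degrades by
construction.

Sequences are laid out with a notional TSS at 70% of the sequence length,
mirroring the asymmetric (-700/+300 of 1,000 nt) promoter window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import SeqRecord
from .negatives import build_binary_dataset

__all__ = [
    "SpeciesProfile",
    "generate_promoters",
    "generate_background",
    "default_profiles",
    "generate_full_fixture",
    "motif_scan_predict",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_TSS_FRACTION = 0.7  # mirrors the -700/+300 window layout


@dataclass(frozen=True)
class SpeciesProfile:
    """Generative profile of one pseudo-species.

    ``motifs`` is a list of (pattern, offset, mutation_probability):
    the pattern is written at the offset (from the sequence start) and each
    of its positions is replaced by a random different base with the given
    probability. ``gc_sd`` spreads the background GC fraction per sequence
    (truncated normal around ``background_gc``), emulating the broad,
    overlapping GC distributions of real promoter sets; at 0 the
    background is i.i.d. at exactly ``background_gc``. ``jitter`` shifts
    each motif's placement per sequence by a uniform offset in
    [-jitter, +jitter], emulating the variable positioning of core
    promoter elements relative to the TSS; at 0 placement is exact.
    """

    name: str
    length: int = 1000
    motifs: tuple[tuple[str, int, float], ...] = ()
    background_gc: float = 0.5
    gc_sd: float = 0.0
    jitter: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.background_gc < 1.0:
            raise ValueError("background_gc must be in (0, 1)")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")
        for pattern, offset, p_mut in self.motifs:
            if (offset - self.jitter < 0
                    or offset + self.jitter + len(pattern) > self.length):
                raise ValueError(
                    f"motif {pattern!r} at offset {offset} (jitter "
                    f"{self.jitter}) does not fit in length {self.length}"
                )
            if not 0.0 <= p_mut <= 0.5:
                raise ValueError("mutation probability must be in [0, 0.5]")
            if set(pattern) - set("ACGT"):
                raise ValueError(f"motif {pattern!r} has non-ACGT characters")


def _background_probs(gc: float) -> np.ndarray:
    at = (1.0 - gc) / 2.0
    return np.array([at, gc / 2.0, gc / 2.0, at])  # A, C, G, T


def generate_promoters(
    profile: SpeciesProfile, n: int, seed: int, label: int = 1
) -> list[SeqRecord]:
    """Draw ``n`` motif-bearing sequences from a profile, deterministically."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    if profile.gc_sd > 0:
        gcs = np.clip(
            rng.normal(profile.background_gc, profile.gc_sd, size=n), 0.15, 0.85
        )
    else:
        gcs = np.full(n, profile.background_gc)
    probs = np.stack([_background_probs(g) for g in gcs])  # (n, 4)
    cum = np.cumsum(probs, axis=1)
    u = rng.random((n, profile.length))
    codes = (u[:, :, None] > cum[:, None, :]).sum(axis=2).astype(np.uint8)
    for pattern, offset, p_mut in profile.motifs:
        motif = np.frombuffer(pattern.encode("ascii"), dtype=np.uint8)
        motif_codes = np.searchsorted(_BASES, motif).astype(np.uint8)
        block = np.tile(motif_codes, (n, 1))
        if p_mut > 0:
            mutate = rng.random((n, len(pattern))) < p_mut
            # replacement is uniform over the three *other* bases
            shift = rng.integers(1, 4, size=(n, len(pattern)))
            block = np.where(mutate, (block + shift) % 4, block).astype(np.uint8)
        if profile.jitter > 0:
            starts = offset + rng.integers(
                -profile.jitter, profile.jitter + 1, size=n
            )
        else:
            starts = np.full(n, offset)
        for i in range(n):
            codes[i, starts[i] : starts[i] + len(pattern)] = block[i]
    out = []
    for i in range(n):
        bases = _BASES[codes[i]].tobytes().decode("ascii")
        out.append(
            SeqRecord(
                id=f"{profile.name}_prom_{i}",
                bases=bases,
                species=profile.name,
                label=label,
            )
        )
    return out


def generate_background(
    profile: SpeciesProfile, n: int, seed: int
) -> list[SeqRecord]:
    """Motif-free i.i.d. sequences matching the profile's composition."""
    plain = SpeciesProfile(
        name=profile.name,
        length=profile.length,
        motifs=(),
        background_gc=profile.background_gc,
        gc_sd=profile.gc_sd,
        jitter=0,
    )
    recs = generate_promoters(plain, n, seed, label=0)
    for i, rec in enumerate(recs):
        rec.id = f"{profile.name}_bg_{i}"
    return recs


def default_profiles(length: int = 1000) -> list[SpeciesProfile]:
    """Three pseudo-species echoing yeast, plant and human promoter signals.

    Motif offsets are anchored upstream of a notional TSS at 70% of the
    sequence length; patterns and background GC are pairwise distinct so a
    classifier trained on one profile transfers poorly to another.
    """
    tss = int(length * _TSS_FRACTION)

    def at(rel: int) -> int:
        return max(0, tss + rel)

    return [
        SpeciesProfile(
            name="unicell",
            length=length,
            motifs=(
                ("TATATAAAGGTA", at(-50), 0.10),  # TATA-box-like element
                ("CAAGAACAAACT", at(20), 0.10),
            ),
            background_gc=0.38,
            gc_sd=0.07,
            jitter=12,
        ),
        SpeciesProfile(
            name="plantlike",
            length=length,
            motifs=(
                ("TCACGTGGCAAT", at(-120), 0.10),  # G-box-like element
                ("CCAATTGGACCA", at(-80), 0.10),
            ),
            background_gc=0.36,
            gc_sd=0.07,
            jitter=12,
        ),
        SpeciesProfile(
            name="mammal",
            length=length,
            motifs=(
                ("GGGGCGGGGCGG", at(-55), 0.10),  # GC-box-like element
                ("GGCCAATCAGGA", at(-90), 0.10),
            ),
            background_gc=0.46,
            gc_sd=0.07,
            jitter=12,
        ),
    ]


def motif_scan_predict(
    records, profile: SpeciesProfile, max_mismatch: int | None = None
) -> np.ndarray:
    """One-rule classifier: primary motif present at its offset, with slack.

    Scores a record positive when the profile's first motif matches at its
    planted offset with at most ``max_mismatch`` mismatches (default: 30%
    of the motif length). This is the independent learnability oracle for
    the fixtures, not a model.
    """
    pattern, offset, _ = profile.motifs[0]
    if max_mismatch is None:
        max_mismatch = int(len(pattern) * 0.3)
    motif = np.frombuffer(pattern.encode("ascii"), dtype=np.uint8)
    w = len(pattern)
    preds = np.zeros(len(records), dtype=np.int64)
    for i, rec in enumerate(records):
        arr = np.frombuffer(rec.bases.encode("ascii"), dtype=np.uint8)
        lo = max(0, offset - profile.jitter)
        hi = min(len(arr) - w, offset + profile.jitter)
        for start in range(lo, hi + 1):
            if int((arr[start : start + w] != motif).sum()) <= max_mismatch:
                preds[i] = 1
                break
    return preds


def generate_full_fixture(
    n_per_class: int = 1000,
    length: int = 250,
    seed: int = 0,
    n_background: int = 600,
    shuffle_mode: str = "mononucleotide",
) -> dict[str, dict[str, list[SeqRecord]]]:
    """Binary datasets plus background pools for the three default profiles.

    For each profile: ``promoters`` (n_per_class motif-bearing sequences),
    ``binary`` (promoters + paired shuffled negatives, 2 * n_per_class
    records), and ``background`` (n_background composition-matched random
    sequences for negative-control testing). Byte-identical under a fixed
    seed.
    """
    root = np.random.SeedSequence(seed)
    out: dict[str, dict[str, list[SeqRecord]]] = {}
    profiles = default_profiles(length=length)
    child_seeds = root.generate_state(3 * len(profiles))
    for i, profile in enumerate(profiles):
        s_prom, s_shuf, s_bg = (int(x) for x in child_seeds[3 * i : 3 * i + 3])
        promoters = generate_promoters(profile, n_per_class, seed=s_prom)
        binary = build_binary_dataset(promoters, mode=shuffle_mode, seed=s_shuf)
        background = generate_background(profile, n_background, seed=s_bg)
        out[profile.name] = {
            "promoters": promoters,
            "binary": binary,
            "background": background,
        }
    return out
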