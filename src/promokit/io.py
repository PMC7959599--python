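"""Reading, cleaning and windowing of promoter sequence data.

Sequences are plain A/C/G/T strings carried in :class:`SeqRecord` objects.
Promoter windows are computed around transcription start sites (TSSs) with
the conventional asymmetric window (default 700 bp upstream, 300 bp
downstream, i.e. positions -700..+300 relative to the TSS), and random
genomic windows can be drawn as an alternative negative / test set.

Coordinates are 0-based half-open throughout, matching BED.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

__all__ = [
    "SeqRecord",
    "GenomicInterval",
    "read_fasta",
    "write_fasta",
    "clean_records",
    "promoter_interval",
    "extract_promoters",
    "read_tss_bed",
    "sample_random_subsequences",
]

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class SeqRecord:
    """One labelled nucleotide sequence.

    Parameters
    ----------
    id : str
        Identifier (text up to the first whitespace of a FASTA header).
    bases : str
        Uppercase nucleotide string.
    species : str, optional
        Categorical species tag.
    label : int, optional
        Class label: 1 = promoter / 0 = non-promoter for binary tasks,
        or a species index for multiclass tasks.
    description : str
        Full FASTA header (defaults to the id).
    """

    id: str
    bases: str
    species: str | None = None
    label: int | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.description:
            self.description = self.id

    def __len__(self) -> int:
        return len(self.bases)

    def is_clean(self) -> bool:
        return len(self.bases) > 0 and set(self.bases) <= VALID_BASES


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval with strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"interval start {self.start} < 0")
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def reverse_complement(bases: str) -> str:
    return bases.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file into a list of :class:`SeqRecord`.

    Headers become ids (up to the first whitespace; the full header is kept
    as ``description``), bases are uppercased, entry order is preserved.
    A ``|label=<int>|`` or ``|species=<tag>|`` field embedded in the header
    (as written by :func:`write_fasta`) is parsed back into the record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: list[SeqRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        bases = str(entry.seq).upper()
        if not bases:
            raise ValueError(f"empty sequence for record {entry.id!r} in {path}")
        rec = SeqRecord(id=entry.id, bases=bases, description=entry.description)
        plain_tokens = []
        for token in entry.id.split("|"):
            if token.startswith("label="):
                rec.label = int(token[len("label="):])
            elif token.startswith("species="):
                rec.species = token[len("species="):]
            else:
                plain_tokens.append(token)
        rec.id = "|".join(plain_tokens)
        records.append(rec)
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path) -> None:
    """Write records to FASTA; labels/species are carried in the header.

    Round-trips through :func:`read_fasta` to equal (id, bases, species,
    label) tuples.
    """
    path = Path(path)
    out = []
    for rec in records:
        header = rec.id
        if rec.label is not None:
            header += f"|label={rec.label}"
        if rec.species is not None:
            header += f"|species={rec.species}"
        out.append(BioSeqRecord(Seq(rec.bases), id=header, description=""))
    with open(path, "w") as fh:
        SeqIO.write(out, fh, "fasta")


def clean_records(
    records: Sequence[SeqRecord], required_length: int
) -> list[SeqRecord]:
    """Keep only records of exactly ``required_length`` clean A/C/G/T bases.

    Filtering, not failure: invalid records are dropped and the counts per
    reason are logged. Idempotent; output is a subset of the input.
    """
    if required_length <= 0:
        raise ValueError("required_length must be positive")
    kept: list[SeqRecord] = []
    n_badlen = n_badchar = 0
    for rec in records:
        if len(rec.bases) != required_length:
            n_badlen += 1
        elif not set(rec.bases) <= VALID_BASES:
            n_badchar += 1
        else:
            kept.append(rec)
    if n_badlen or n_badchar:
        logger.info(
            "clean_records: dropped %d wrong-length and %d non-ACGT records "
            "(%d kept)", n_badlen, n_badchar, len(kept),
        )
    return kept


def promoter_interval(
    tss: int,
    strand: str,
    chrom: str = "",
    upstream: int = 700,
    downstream: int = 300,
) -> GenomicInterval:
    """Window of ``upstream`` bp before and ``downstream`` bp after a TSS.

    On the minus strand the offsets are mirrored (upstream is to the right
    of the TSS in genome coordinates); the caller reverse-complements the
    extracted sequence. The interval length is always
    ``upstream + downstream``.
    """
    if strand == "+":
        start, end = tss - upstream, tss + downstream
    elif strand == "-":
        start, end = tss - downstream, tss + upstream
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if start < 0:
        raise ValueError(
            f"promoter window [{start}, {end}) extends below coordinate 0 "
            f"(tss={tss}, strand={strand})"
        )
    return GenomicInterval(chrom=chrom, start=start, end=end, strand=strand)


def read_tss_bed(path: str | Path) -> list[tuple[str, int, str, str]]:
    """Read a 6-column BED of features; the TSS is the strand-aware 5' end.

    Returns tuples ``(chrom, tss, strand, name)``.
    """
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{i}: need 6 BED columns, got {len(fields)}")
            chrom, start, end, name, _score, strand = fields[:6]
            start_i, end_i = int(start), int(end)
            tss = start_i if strand == "+" else end_i - 1
            rows.append((chrom, tss, strand, name))
    return rows


def extract_promoters(
    genome: Sequence[SeqRecord],
    tss_table: Sequence[tuple[str, int, str, str]],
    upstream: int = 700,
    downstream: int = 300,
) -> list[SeqRecord]:
    """Extract promoter windows around TSSs from a genome.

    Minus-strand windows are reverse-complemented so that every returned
    sequence reads 5'->3' from -upstream to +downstream relative to its TSS.
    Windows that fall outside their chromosome are skipped with a log entry.
    """
    chroms = {rec.id: rec.bases for rec in genome}
    out: list[SeqRecord] = []
    n_skipped = 0
    for chrom, tss, strand, name in tss_table:
        if chrom not in chroms:
            raise KeyError(f"chromosome {chrom!r} not present in genome")
        try:
            iv = promoter_interval(tss, strand, chrom, upstream, downstream)
        except ValueError:
            n_skipped += 1
            continue
        seq = chroms[chrom][iv.start : iv.end]
        if len(seq) < len(iv):
            n_skipped += 1
            continue
        if strand == "-":
            seq = reverse_complement(seq)
        out.append(SeqRecord(id=name, bases=seq))
    if n_skipped:
        logger.info("extract_promoters: skipped %d out-of-bounds windows", n_skipped)
    return out


def sample_random_subsequences(
    genome: Sequence[SeqRecord],
    n: int,
    length: int,
    seed: int,
    max_rejects_per_draw: int = 1000,
) -> list[SeqRecord]:
    """Draw ``n`` random length-``length`` A/C/G/T windows from a genome.

    Positions are uniform over all valid (sequence, offset) pairs on the
    forward strand; windows containing a non-ACGT character are rejected
    and redrawn. Deterministic under ``seed``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    sources = [rec for rec in genome if len(rec.bases) >= length]
    if not sources:
        raise ValueError(
            f"no genome sequence is at least {length} nt long; cannot sample"
        )
    rng = np.random.default_rng(seed)
    n_offsets = np.array([len(rec.bases) - length + 1 for rec in sources])
    cum = np.cumsum(n_offsets)
    total = int(cum[-1])
    out: list[SeqRecord] = []
    budget = n * max_rejects_per_draw
    while len(out) < n:
        if budget <= 0:
            raise RuntimeError(
                "rejection budget exhausted while sampling random windows: "
                "the genome is too dense in non-ACGT (e.g. N) characters"
            )
        flat = int(rng.integers(total))
        si = int(np.searchsorted(cum, flat, side="right"))
        offset = flat - (int(cum[si - 1]) if si else 0)
        window = sources[si].bases[offset : offset + length]
        budget -= 1
        if set(window) <= VALID_BASES:
            out.append(
                SeqRecord(
                    id=f"rand_{len(out)}_{sources[si].id}_{offset}",
                    bases=window,
                    label=0,
                )
            )
    return out
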