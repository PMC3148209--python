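"""Per-position pileup of SAM alignments against a reference.

Converts a coordinate-sorted SAM stream plus the reference FASTA into
pileup columns carrying, for every covered position, the per-allele
strand-resolved base counts, base qualities, and anchored insertion and
deletion evidence.  This is the substrate of the variant filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pysam
from Bio import SeqIO

DEFAULT_MIN_MAPQ = 10

BASES = ("A", "C", "G", "T")


def load_reference(path: str) -> dict[str, str]:
    """Read a FASTA into an uppercase chrom -> sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


@dataclass
class PileupColumn:
    """Allele/strand/quality tallies at one reference position.

    ``base_evidence`` maps a base to the list of supporting observations as
    ``(strand, qual)`` pairs (``qual`` is ``None`` when the SAM record has
    no quality string); ``insertions`` maps an inserted sequence (anchored
    after this position) to its ``[plus, minus]`` counts; ``deletions``
    maps a deletion length (starting at this position) to its
    ``[plus, minus]`` counts.
    """

    chrom: str
    pos: int
    ref_base: str
    base_evidence: dict[str, list[tuple[str, int | None]]] = field(
        default_factory=dict)
    insertions: dict[str, list[int]] = field(default_factory=dict)
    deletions: dict[int, list[int]] = field(default_factory=dict)

    @property
    def base_counts(self) -> dict[str, tuple[int, int]]:
        """Per-base (plus, minus) strand counts."""
        return {b: (sum(1 for s, _ in obs if s == "+"),
                    sum(1 for s, _ in obs if s == "-"))
                for b, obs in self.base_evidence.items() if obs}

    @property
    def base_quals(self) -> dict[str, list[int]]:
        """Per-base Phred scores, order of observation."""
        return {b: [q for _, q in obs if q is not None]
                for b, obs in self.base_evidence.items() if obs}

    @property
    def depth(self) -> int:
        """Reads contributing base evidence at this position."""
        return sum(len(obs) for obs in self.base_evidence.values())

    @property
    def deletion_depth(self) -> int:
        """Reads whose deletion spans start at this position."""
        return sum(p + m for p, m in self.deletions.values())

    def add_base(self, base: str, strand: str, qual: int | None) -> None:
        self.base_evidence.setdefault(base, []).append((strand, qual))

    def add_insertion(self, seq: str, strand: str) -> None:
        counts = self.insertions.setdefault(seq, [0, 0])
        counts[0 if strand == "+" else 1] += 1

    def add_deletion(self, length: int, strand: str) -> None:
        counts = self.deletions.setdefault(length, [0, 0])
        counts[0 if strand == "+" else 1] += 1


class UnsortedInputError(ValueError):
    """SAM records are not in coordinate order."""


def _strand(read: pysam.AlignedSegment) -> str:
    return "-" if read.is_reverse else "+"


def pileup_from_sam(sam_path: str, reference: dict[str, str] | str,
                    min_mapq: int = DEFAULT_MIN_MAPQ):
    """Yield :class:`PileupColumn` objects in coordinate order.

    Reads below ``min_mapq`` (inclusive threshold: kept when mapq >= cutoff),
    unmapped reads and secondary/supplementary alignments are excluded.
    M/=/X operations contribute base evidence, I operations record the
    inserted sequence at the preceding aligned column, D operations record
    deletion evidence at the first deleted position; S/H/N contribute
    nothing.
    """
    if isinstance(reference, str):
        reference = load_reference(reference)
    columns: dict[int, PileupColumn] = {}
    cur_chrom: str | None = None
    last_start = -1

    def get_col(chrom: str, pos: int) -> PileupColumn:
        col = columns.get(pos)
        if col is None:
            ref_seq = reference[chrom]
            ref_base = ref_seq[pos] if pos < len(ref_seq) else "N"
            col = PileupColumn(chrom=chrom, pos=pos, ref_base=ref_base)
            columns[pos] = col
        return col

    def flush(before: int | None):
        for pos in sorted(columns):
            if before is not None and pos >= before:
                break
            yield columns.pop(pos)

    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        for read in sam:
            if (read.is_unmapped or read.is_secondary
                    or read.is_supplementary):
                continue
            if read.mapping_quality < min_mapq:
                continue
            chrom = read.reference_name
            if chrom not in reference:
                raise KeyError(f"chromosome {chrom!r} missing from reference")
            if chrom != cur_chrom:
                yield from flush(None)
                cur_chrom = chrom
                last_start = -1
            if read.reference_start < last_start:
                raise UnsortedInputError(
                    f"{read.query_name} at {chrom}:{read.reference_start} "
                    "breaks coordinate order")
            last_start = read.reference_start
            yield from flush(read.reference_start)
            _accumulate(read, get_col, chrom)
    yield from flush(None)


def _accumulate(read: pysam.AlignedSegment, get_col, chrom: str) -> None:
    strand = _strand(read)
    seq = read.query_sequence or ""
    quals = read.query_qualities  # None when the quality string is '*'
    rpos = read.reference_start
    qpos = 0
    last_aligned = None
    for op, length in read.cigartuples or []:
        if op in (0, 7, 8):  # M, =, X
            for k in range(length):
                q = quals[qpos + k] if quals is not None else None
                get_col(chrom, rpos + k).add_base(seq[qpos + k], strand, q)
            last_aligned = rpos + length - 1
            rpos += length
            qpos += length
        elif op == 1:  # I: anchored after the previous aligned base
            if last_aligned is not None:
                get_col(chrom, last_aligned).add_insertion(
                    seq[qpos:qpos + length], strand)
            qpos += length
        elif op == 2:  # D: evidence at the first deleted position
            get_col(chrom, rpos).add_deletion(length, strand)
            rpos += length
        elif op == 3:  # N: skip, no evidence
            rpos += length
        elif op == 4:  # S
            qpos += length
        # H (5) and P (6) consume nothing we track
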