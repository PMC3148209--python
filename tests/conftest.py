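"""Shared fixtures and builders for the test suite.

All fixtures are generated programmatically; SAM/FASTA/GTF content is
written into pytest tmp directories at test time.
"""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from seqmine.annotation import AnnotationIndex, TranscriptModel
from seqmine.pileup import BASES, PileupColumn


def make_column(ref_base: str = "A", chrom: str = "chr1", pos: int = 100,
                bases=(), insertions=(), deletions=()) -> PileupColumn:
    """Build a pileup column from (base, strand, qual) observation tuples.

    ``insertions``/``deletions`` are (allele, strand) tuples (allele is the
    inserted sequence or the deletion length).
    """
    col = PileupColumn(chrom=chrom, pos=pos, ref_base=ref_base)
    for base, strand, qual in bases:
        col.add_base(base, strand, qual)
    for seq, strand in insertions:
        col.add_insertion(seq, strand)
    for length, strand in deletions:
        col.add_deletion(length, strand)
    return col


def random_column(rng: np.random.Generator) -> PileupColumn:
    """A random pileup column exercising every branch of the filter."""
    ref = BASES[rng.integers(4)]
    col = PileupColumn(chrom="chr1", pos=int(rng.integers(1_000_000)),
                       ref_base=ref)
    depth = int(rng.integers(0, 40))
    alt = BASES[rng.integers(4)]
    for _ in range(depth):
        base = alt if rng.random() < 0.35 else ref
        strand = "+" if rng.random() < rng.uniform(0.05, 0.95) else "-"
        qual = int(rng.integers(0, 41)) if rng.random() < 0.9 else None
        col.add_base(base, strand, qual)
    if rng.random() < 0.25:
        for _ in range(int(rng.integers(1, 8))):
            col.add_insertion("AC", "+" if rng.random() < 0.5 else "-")
    if rng.random() < 0.25:
        for _ in range(int(rng.integers(1, 8))):
            col.add_deletion(2, "+" if rng.random() < 0.5 else "-")
    return col


def write_sam(path, reads, chrom="chr1", length=10_000):
    """Write aligned reads given as (qname, pos, cigar, seq, qual, flag, mapq).

    ``qual`` may be None (written as '*'); ``cigar`` is a cigartuples list.
    """
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": chrom, "LN": length}]}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for qname, pos, cigar, seq, qual, flag, mapq in reads:
            a = pysam.AlignedSegment(
                header=pysam.AlignmentHeader.from_dict(header))
            a.query_name = qname
            a.query_sequence = seq
            a.flag = flag
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = mapq
            a.cigartuples = cigar
            if qual is not None:
                a.query_qualities = pysam.qualitystring_to_array(qual)
            out.write(a)
    return str(path)


@pytest.fixture
def simple_reference() -> dict[str, str]:
    rng = np.random.default_rng(2024)
    return {"chr1": "".join(np.array(list("ACGT"))[
        rng.integers(0, 4, size=10_000)])}


@pytest.fixture
def coding_index(simple_reference) -> AnnotationIndex:
    """Two overlapping coding transcripts plus one noncoding transcript.

    tx1/+: exons [1000,1100) [1200,1300), CDS [1030,1271) (141 bases).
    tx2/+: exons [1040,1100) [1200,1320), CDS [1050,1261) (111 bases).
    nc1/-: single exon [5000,5200), noncoding.
    """
    index = AnnotationIndex(flank_size=500, reference=simple_reference)
    index.add(TranscriptModel("tx1", "geneA", "chr1", "+",
                              [(1000, 1100), (1200, 1300)],
                              cds_start=1030, cds_end=1271))
    index.add(TranscriptModel("tx2", "geneA", "chr1", "+",
                              [(1040, 1100), (1200, 1320)],
                              cds_start=1050, cds_end=1261))
    index.add(TranscriptModel("nc1", "geneB", "chr1", "-",
                              [(5000, 5200)]))
    return index
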