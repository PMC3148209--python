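"""Gene-model annotation of genomic positions and coding consequences.

Transcript models are loaded from GTF or BED12 and indexed per chromosome so
that any position can be classified into the usual gene-model categories
(upstream, downstream, UTRs, coding exon, intron, splice site, intergenic,
noncoding exon).  Substitutions and small indels falling in coding sequence
are translated into protein-level consequences (synonymous, missense,
nonsense, frameshift, in-frame indel).

All coordinates are 0-based half-open internally; GTF (1-based inclusive)
is converted at the boundary, BED12 already matches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio.Seq import Seq
from Bio.SeqUtils import seq3
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: bases of intron, at each exon/intron boundary, called splice site
SPLICE_WINDOW = 2

#: default upstream/downstream flank, bases
DEFAULT_FLANK = 1000

REGION_UPSTREAM = "upstream"
REGION_DOWNSTREAM = "downstream"
REGION_UTR5 = "5'UTR"
REGION_UTR3 = "3'UTR"
REGION_CODING = "exon_coding"
REGION_INTRON = "intron"
REGION_SPLICE = "splice_site"
REGION_INTERGENIC = "intergenic"
REGION_NONCODING = "noncoding_exon"


class ParseError(ValueError):
    """Raised when a gene-model file cannot be parsed."""


@dataclass
class TranscriptModel:
    """A transcript: ordered exons, optional CDS bounds, strand.

    ``exons`` are non-overlapping, sorted 0-based half-open genomic
    intervals.  ``cds_start``/``cds_end`` are genomic bounds of the coding
    region (``None`` for non-coding transcripts).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        if not self.exons or any(b <= a for a, b in self.exons):
            raise ValueError(f"{self.transcript_id}: invalid exon structure")
        for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None and self.cds_end is not None

    def exon_containing(self, pos: int) -> tuple[int, int] | None:
        for s, e in self.exons:
            if s <= pos < e:
                return (s, e)
        return None

    def cds_intervals(self) -> list[tuple[int, int]]:
        """Exon pieces intersected with the CDS bounds, genomic order."""
        if not self.is_coding:
            return []
        out = []
        for s, e in self.exons:
            s2, e2 = max(s, self.cds_start), min(e, self.cds_end)
            if s2 < e2:
                out.append((s2, e2))
        return out

    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals())

    def genomic_to_cds(self, pos: int) -> int | None:
        """Map a genomic position to a 0-based offset in the stranded CDS."""
        off = 0
        hit = None
        for s, e in self.cds_intervals():
            if s <= pos < e:
                hit = off + (pos - s)
            elif pos >= e:
                pass
            off += e - s
        if hit is None:
            return None
        return hit if self.strand == "+" else self.cds_length() - 1 - hit

    def cds_sequence(self, reference: dict[str, str]) -> str:
        """Spliced CDS in translation orientation from a chrom->seq mapping."""
        seq = "".join(reference[self.chrom][s:e] for s, e in self.cds_intervals())
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def position_in_transcript(self, pos: int) -> int | None:
        """0-based offset of an exonic position in the stranded transcript."""
        off = 0
        hit = None
        for s, e in self.exons:
            if s <= pos < e:
                hit = off + (pos - s)
            off += e - s
        if hit is None:
            return None
        return hit if self.strand == "+" else self.length - 1 - hit


@dataclass
class FunctionalAnnotation:
    """Annotation of one position/variant on one overlapping transcript."""

    transcript_id: str
    region: str
    consequence: str = "none"
    codon_number: int | None = None
    amino_acid_change: str | None = None
    position_in_transcript: int | None = None


class AnnotationIndex:
    """Per-chromosome interval index over transcript models (span + flank)."""

    def __init__(self, flank_size: int = DEFAULT_FLANK,
                 reference: dict[str, str] | None = None):
        self.flank_size = int(flank_size)
        self.reference = reference
        self.transcripts: dict[str, TranscriptModel] = {}
        self._trees: dict[str, IntervalTree] = {}
        self._warned_chroms: set[str] = set()

    def add(self, model: TranscriptModel) -> None:
        self.transcripts[model.transcript_id] = model
        tree = self._trees.setdefault(model.chrom, IntervalTree())
        tree.addi(max(0, model.start - self.flank_size),
                  model.end + self.flank_size, model)

    def __len__(self) -> int:
        return len(self.transcripts)

    def overlapping(self, chrom: str, pos: int) -> list[TranscriptModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            if chrom not in self._warned_chroms:
                logger.warning("chromosome %s not in annotation", chrom)
                self._warned_chroms.add(chrom)
            return []
        hits = [iv.data for iv in tree.at(pos)]
        return sorted(hits, key=lambda t: t.transcript_id)

    def all_exons(self) -> list[tuple[str, int, int]]:
        """Unique (chrom, start, end) exon intervals over all transcripts."""
        seen = sorted({(t.chrom, s, e)
                       for t in self.transcripts.values() for s, e in t.exons})
        return seen


def _classify_in_transcript(t: TranscriptModel, pos: int) -> str:
    if pos < t.start:
        return REGION_UPSTREAM if t.strand == "+" else REGION_DOWNSTREAM
    if pos >= t.end:
        return REGION_DOWNSTREAM if t.strand == "+" else REGION_UPSTREAM
    exon = t.exon_containing(pos)
    if exon is not None:
        if not t.is_coding:
            return REGION_NONCODING
        if t.cds_start <= pos < t.cds_end:
            return REGION_CODING
        if pos < t.cds_start:
            return REGION_UTR5 if t.strand == "+" else REGION_UTR3
        return REGION_UTR3 if t.strand == "+" else REGION_UTR5
    # intronic: measure distance to the flanking exon boundaries
    prev_end = max(e for _, e in t.exons if e <= pos)
    next_start = min(s for s, _ in t.exons if s > pos)
    if pos - prev_end < SPLICE_WINDOW or next_start - pos <= SPLICE_WINDOW:
        return REGION_SPLICE
    return REGION_INTRON


def classify_site(index: AnnotationIndex, chrom: str, pos: int
                  ) -> list[FunctionalAnnotation]:
    """Region-level annotation of a position on every overlapping transcript.

    Returns one record per transcript whose span +/- flank covers ``pos``;
    an empty list means the position is intergenic.
    """
    out = []
    for t in index.overlapping(chrom, pos):
        region = _classify_in_transcript(t, pos)
        out.append(FunctionalAnnotation(
            transcript_id=t.transcript_id, region=region,
            position_in_transcript=t.position_in_transcript(pos)))
    return out


def coding_consequence(reference_cds: str, pos_in_cds: int, ref: str, alt: str,
                       transcript_id: str = "") -> FunctionalAnnotation:
    """Protein-level consequence of a variant inside the coding sequence.

    ``alt`` is a single base for substitutions, ``+SEQ`` for an insertion
    after ``pos_in_cds``, or ``-N`` for a deletion of N bases starting at
    ``pos_in_cds``.  ``reference_cds`` and the alleles are in translation
    orientation (the caller reverse-complements for minus-strand models).
    """
    reference_cds = reference_cds.upper()
    if len(reference_cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    codon_number = pos_in_cds // 3 + 1
    ann = FunctionalAnnotation(transcript_id=transcript_id,
                               region=REGION_CODING,
                               codon_number=codon_number)
    if alt.startswith("+"):
        indel_len = len(alt) - 1
        ann.consequence = "frameshift" if indel_len % 3 else "inframe_indel"
        return ann
    if alt.startswith("-"):
        indel_len = int(alt[1:])
        ann.consequence = "frameshift" if indel_len % 3 else "inframe_indel"
        return ann
    ref = ref.upper()
    alt = alt.upper()
    if reference_cds[pos_in_cds] != ref:
        raise ValueError(
            f"reference allele mismatch at CDS position {pos_in_cds}: "
            f"expected {reference_cds[pos_in_cds]}, got {ref}")
    frame = pos_in_cds % 3
    codon_start = pos_in_cds - frame
    codon = reference_cds[codon_start:codon_start + 3]
    new_codon = codon[:frame] + alt + codon[frame + 1:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(new_codon).translate())
    if aa_ref == aa_alt:
        ann.consequence = "synonymous"
    elif aa_alt == "*":
        ann.consequence = "nonsense"
    else:
        ann.consequence = "missense"
    name = lambda aa: "Stop" if aa == "*" else seq3(aa)
    ann.amino_acid_change = f"{name(aa_ref)}->{name(aa_alt)}"
    return ann


# ---------------------------------------------------------------------------
# gene-model file loading


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for part in text.strip().rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def _load_gtf(path: str) -> list[TranscriptModel]:
    exons: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 "
                                 f"tab-separated fields, got {len(fields)}")
            chrom, _, feat, start, end, _, strand, _, attr_text = fields[:9]
            if feat not in ("exon", "CDS"):
                continue
            try:
                start_i, end_i = int(start) - 1, int(end)  # GTF is 1-based
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: bad coordinates") from exc
            attrs = _parse_gtf_attributes(attr_text)
            tid = attrs.get("transcript_id")
            if tid is None:
                raise ParseError(f"{path}: line {lineno}: missing transcript_id")
            rec = exons.setdefault(tid, {
                "gene_id": attrs.get("gene_id", tid), "chrom": chrom,
                "strand": strand, "exons": [], "cds": []})
            if feat == "exon":
                rec["exons"].append((start_i, end_i))
            else:
                rec["cds"].append((start_i, end_i))
    models = []
    for tid, rec in exons.items():
        if not rec["exons"]:
            logger.warning("transcript %s has zero exons; skipped", tid)
            continue
        cds_start = cds_end = None
        if rec["cds"]:
            cds_start = min(s for s, _ in rec["cds"])
            cds_end = max(e for _, e in rec["cds"])
        models.append(TranscriptModel(
            transcript_id=tid, gene_id=rec["gene_id"], chrom=rec["chrom"],
            strand=rec["strand"], exons=rec["exons"],
            cds_start=cds_start, cds_end=cds_end))
    return models


def _load_bed12(path: str) -> list[TranscriptModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(f"{path}: line {lineno}: BED12 needs 12 "
                                 f"fields, got {len(fields)}")
            try:
                chrom = fields[0]
                start = int(fields[1])
                name = fields[3]
                strand = fields[5]
                thick_start, thick_end = int(fields[6]), int(fields[7])
                block_count = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: bad BED12 fields") from exc
            if not (len(sizes) == len(starts) == block_count):
                raise ParseError(f"{path}: line {lineno}: blockCount does not "
                                 "match blockSizes/blockStarts")
            if block_count == 0:
                logger.warning("line %d: zero blocks; skipped", lineno)
                continue
            exon_list = [(start + bs, start + bs + sz)
                         for bs, sz in zip(starts, sizes)]
            cds_start = cds_end = None
            if thick_start < thick_end:
                cds_start, cds_end = thick_start, thick_end
            models.append(TranscriptModel(
                transcript_id=name, gene_id=name, chrom=chrom, strand=strand,
                exons=exon_list, cds_start=cds_start, cds_end=cds_end))
    return models


def load_gene_models(path: str, flank_size: int = DEFAULT_FLANK,
                     reference: dict[str, str] | None = None,
                     fmt: str | None = None) -> AnnotationIndex:
    """Load transcript models from GTF or BED12 into an interval index.

    The format is taken from the file extension unless ``fmt`` ("gtf" or
    "bed") is given.  ``reference`` (chrom -> sequence) enables coding-
    consequence annotation downstream.
    """
    if fmt is None:
        low = path.lower()
        fmt = "bed" if low.endswith((".bed", ".bed12")) else "gtf"
    models = _load_bed12(path) if fmt == "bed" else _load_gtf(path)
    index = AnnotationIndex(flank_size=flank_size, reference=reference)
    for m in models:
        index.add(m)
    return index


def write_bed12(index: AnnotationIndex, path: str) -> None:
    """Write the indexed transcript models as BED12."""
    with open(path, "w") as fh:
        for tid in sorted(index.transcripts):
            t = index.transcripts[tid]
            thick_start = t.cds_start if t.is_coding else t.start
            thick_end = t.cds_end if t.is_coding else t.start
            sizes = ",".join(str(e - s) for s, e in t.exons)
            starts = ",".join(str(s - t.start) for s, _ in t.exons)
            fh.write("\t".join(map(str, [
                t.chrom, t.start, t.end, t.transcript_id, 0, t.strand,
                thick_start, thick_end, "0", len(t.exons), sizes, starts,
            ])) + "\n")


def load_known_sites(path: str) -> dict[tuple[str, int, str, str], str]:
    """Read a VCF of known variant sites into a (chrom,pos,ref,alt)->ID map.

    Only CHROM, POS, ID, REF and ALT are used; POS is converted to the
    internal 0-based convention.  Multi-allelic records contribute one key
    per ALT allele.
    """
    sites: dict[tuple[str, int, str, str], str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise ParseError(f"{path}: truncated VCF record: {line!r}")
            chrom, pos, vid, ref, alts = fields[:5]
            for alt in alts.split(","):
                sites[(chrom, int(pos) - 1, ref, alt)] = vid
    return sites
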