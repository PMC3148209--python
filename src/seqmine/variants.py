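"""The four-criterion mutation filter, genotype calling and call annotation.

A candidate site passes when, after low-quality base calls are removed from
the coverage:

1. the effective coverage reaches ``min_coverage`` (default 20 reads);
2. base calls below ``min_base_qual`` (default Phred 10) have been masked
   out (this criterion acts through the masking itself);
3. the minor sequenced-strand frequency of the alternate-supporting reads,
   min(plus, minus) / (plus + minus), reaches ``min_minor_strand_freq``
   (default 0.1);
4. the alternate-allele fraction of the effective coverage reaches
   ``min_alt_freq`` (default 0.25).

All comparisons are inclusive (>=): the published defaults are treated as
minima.  Sites that pass are genotyped heterozygous or homozygous mutant by
the alternate-allele fraction; failing candidates are labelled ``qc``;
non-mutated positions are ``hom_ref`` or ``qc`` depending on whether the
coverage clears the same threshold.

Alternate alleles are encoded as a single base for substitutions, ``+SEQ``
for insertions and ``-N`` for deletions; indels are filtered with the same
four criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .annotation import (AnnotationIndex, FunctionalAnnotation, REGION_CODING,
                         coding_consequence)
from .pileup import BASES, PileupColumn

from Bio.Seq import Seq

GT_HET = "het_mut"
GT_HOM = "hom_mut"
GT_REF = "hom_ref"
GT_QC = "qc"

CATEGORIES = (GT_HET, GT_HOM, GT_REF, GT_QC)


@dataclass
class FilterConfig:
    """Thresholds of the mutation filter (all inclusive minima)."""

    min_coverage: int = 20
    min_base_qual: int = 10
    min_minor_strand_freq: float = 0.1
    min_alt_freq: float = 0.25
    hom_alt_freq: float = 0.75

    def __post_init__(self) -> None:
        for name in ("min_minor_strand_freq", "min_alt_freq", "hom_alt_freq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_alt_freq >= self.hom_alt_freq:
            raise ValueError("min_alt_freq must be below hom_alt_freq")


@dataclass
class VariantCall:
    """A filtered, genotyped, annotated mutation record."""

    chrom: str
    pos: int
    ref: str
    alt: str
    effective_depth: int
    alt_count: int
    strand_counts: tuple[int, int]
    alt_freq: float
    genotype: str
    filter_reasons: list[str] = field(default_factory=list)
    ase: dict[str, int] = field(default_factory=dict)
    annotations: list[FunctionalAnnotation] = field(default_factory=list)
    known_id: str | None = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def mask_quality(col: PileupColumn, min_base_qual: int) -> PileupColumn:
    """Remove base calls with Phred quality below the cutoff.

    Observations without a quality score (missing quality string) are kept,
    as masking applies only when qualities are present.  Indel evidence
    carries no base quality and is unaffected.
    """
    masked = PileupColumn(chrom=col.chrom, pos=col.pos, ref_base=col.ref_base)
    for base, obs in col.base_evidence.items():
        kept = [(s, q) for s, q in obs if q is None or q >= min_base_qual]
        if kept:
            masked.base_evidence[base] = kept
    masked.insertions = {k: list(v) for k, v in col.insertions.items()}
    masked.deletions = {k: list(v) for k, v in col.deletions.items()}
    return masked


def _allele_order(allele: str) -> tuple:
    # bases sort before indel alleles; within each class lexicographic
    return (0, allele) if allele in BASES else (1, allele)


def candidate_alt(col: PileupColumn) -> str | None:
    """Highest-count non-reference allele; ties broken A<C<G<T<indel."""
    counts: dict[str, int] = {}
    for base, (p, m) in col.base_counts.items():
        if base != col.ref_base and base != "N":
            counts[base] = p + m
    for seq, (p, m) in col.insertions.items():
        counts[f"+{seq}"] = p + m
    for length, (p, m) in col.deletions.items():
        counts[f"-{length}"] = p + m
    counts = {a: c for a, c in counts.items() if c > 0}
    if not counts:
        return None
    return min(counts, key=lambda a: (-counts[a], _allele_order(a)))


def _alt_strand_counts(col: PileupColumn, alt: str) -> tuple[int, int]:
    if alt.startswith("+"):
        p, m = col.insertions.get(alt[1:], (0, 0))
    elif alt.startswith("-"):
        p, m = col.deletions.get(int(alt[1:]), (0, 0))
    else:
        p, m = col.base_counts.get(alt, (0, 0))
    return int(p), int(m)


def effective_depth(col: PileupColumn) -> int:
    """Reads covering the position after masking.

    Reads whose deletion starts here contribute no base call but do cover
    the position, so they are included; this makes the deletion-allele
    fraction well defined.
    """
    return col.depth + col.deletion_depth


def filter_site(col: PileupColumn, cfg: FilterConfig = FilterConfig()
                ) -> tuple[bool, list[str], PileupColumn]:
    """Apply the four-criterion filter to a candidate pileup column.

    Returns ``(passed, reasons, masked_col)`` where ``reasons`` names every
    failed criterion (``coverage``, ``strand``, ``alt_freq``; a column with
    no remaining non-reference evidence fails with ``no_candidate``).
    """
    masked = mask_quality(col, cfg.min_base_qual)
    depth = effective_depth(masked)
    if depth == 0:
        return False, ["coverage"], masked
    alt = candidate_alt(masked)
    if alt is None:
        return False, ["no_candidate"], masked
    reasons = []
    if depth < cfg.min_coverage:
        reasons.append("coverage")
    plus, minus = _alt_strand_counts(masked, alt)
    alt_total = plus + minus
    if min(plus, minus) / alt_total < cfg.min_minor_strand_freq:
        reasons.append("strand")
    if alt_total / depth < cfg.min_alt_freq:
        reasons.append("alt_freq")
    return not reasons, reasons, masked


def call_genotype(col: PileupColumn, cfg: FilterConfig = FilterConfig()) -> str:
    """Genotype category of a pileup column.

    Candidates passing the filter are het or hom mutant by the alternate
    fraction (boundary ``hom_alt_freq``); failing candidates are ``qc``;
    non-candidates are ``hom_ref`` or ``qc`` by coverage alone.
    """
    masked = mask_quality(col, cfg.min_base_qual)
    depth = effective_depth(masked)
    alt = candidate_alt(masked)
    if alt is None:
        return GT_REF if depth >= cfg.min_coverage else GT_QC
    passed, _, _ = filter_site(col, cfg)
    if not passed:
        return GT_QC
    plus, minus = _alt_strand_counts(masked, alt)
    alt_freq = (plus + minus) / depth
    return GT_HOM if alt_freq >= cfg.hom_alt_freq else GT_HET


def call_variant(col: PileupColumn, cfg: FilterConfig = FilterConfig()
                 ) -> VariantCall | None:
    """Build the full call record for a column, or ``None`` if the column
    carries no non-reference evidence after masking."""
    passed, reasons, masked = filter_site(col, cfg)
    alt = candidate_alt(masked)
    if alt is None:
        return None
    depth = effective_depth(masked)
    plus, minus = _alt_strand_counts(masked, alt)
    alt_total = plus + minus
    alt_freq = alt_total / depth if depth else 0.0
    if passed:
        genotype = GT_HOM if alt_freq >= cfg.hom_alt_freq else GT_HET
    else:
        genotype = GT_QC
    ase = {b: p + m for b, (p, m) in masked.base_counts.items()}
    for seq, (p, m) in masked.insertions.items():
        ase[f"+{seq}"] = p + m
    for length, (p, m) in masked.deletions.items():
        ase[f"-{length}"] = p + m
    return VariantCall(
        chrom=col.chrom, pos=col.pos, ref=col.ref_base, alt=alt,
        effective_depth=depth, alt_count=alt_total,
        strand_counts=(plus, minus), alt_freq=alt_freq, genotype=genotype,
        filter_reasons=[] if passed else reasons, ase=ase)


def call_variants(columns, cfg: FilterConfig = FilterConfig(),
                  candidates_only: bool = True):
    """Run the filter over a pileup column stream, yielding call records."""
    for col in columns:
        call = call_variant(col, cfg)
        if call is None:
            continue
        if candidates_only and call.genotype == GT_QC and \
                "no_candidate" in call.filter_reasons:
            continue
        yield call


def annotate_call(call: VariantCall, index: AnnotationIndex,
                  known_sites: dict[tuple[str, int, str, str], str] | None = None
                  ) -> VariantCall:
    """Attach gene-model annotations, coding consequences and a known-site ID.

    One annotation record is produced per overlapping transcript (a variant
    inside several transcripts is annotated once per transcript).  Coding
    consequences require the index to carry the reference genome; on the
    minus strand the alleles are reverse-complemented before codon lookup.
    """
    from .annotation import classify_site  # local to avoid cycle at import

    anns = classify_site(index, call.chrom, call.pos)
    for ann in anns:
        model = index.transcripts[ann.transcript_id]
        if (ann.region == REGION_CODING and model.is_coding
                and index.reference is not None):
            cds = model.cds_sequence(index.reference)
            if len(cds) % 3:
                continue
            pos_in_cds = model.genomic_to_cds(call.pos)
            if pos_in_cds is None:
                continue
            ref, alt = call.ref, call.alt
            if model.strand == "-":
                ref = str(Seq(ref).reverse_complement())
                if alt.startswith("+"):
                    alt = "+" + str(Seq(alt[1:]).reverse_complement())
                elif not alt.startswith("-"):
                    alt = str(Seq(alt).reverse_complement())
            cons = coding_consequence(cds, pos_in_cds, ref, alt,
                                      transcript_id=ann.transcript_id)
            ann.consequence = cons.consequence
            ann.codon_number = cons.codon_number
            ann.amino_acid_change = cons.amino_acid_change
    call.annotations = anns
    if known_sites is not None:
        call.known_id = known_sites.get(call.key)
    return call
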