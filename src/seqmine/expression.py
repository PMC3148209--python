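"""Coverage tracks, exome QC, RPKM quantification and expression matrices.

Coverage is per-base read depth over the reference; exome QC summarizes
per-exon average coverage (mean depth on exons, fraction of exons at >= 5x
and >= 10x, on-target specificity); expression of transcripts and exons is
reported as raw read counts, mean fold-coverage of the model and RPKM
(reads per kilobase of exon model per million mapped reads):

    RPKM = count / (model_length/1000) / (total_mapped_reads/1e6)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .annotation import AnnotationIndex
from .pileup import DEFAULT_MIN_MAPQ

CoverageTrack = dict[str, np.ndarray]


@dataclass
class ExpressionRecord:
    """Expression of one feature (transcript or exon) in one sample."""

    feature_id: str
    read_count: int
    mean_coverage: float
    rpkm: float


@dataclass
class ExpressionMatrix:
    """Features x samples tables of RPKM and raw counts (shared ordering)."""

    rpkm: pd.DataFrame
    counts: pd.DataFrame

    @property
    def samples(self) -> list[str]:
        return list(self.rpkm.columns)

    @property
    def features(self) -> list[str]:
        return list(self.rpkm.index)


@dataclass
class ExonQCReport:
    """Exome capture quality summary."""

    mean_depth_exons: float
    pct_exons_cov_ge5: float
    pct_exons_cov_ge10: float
    coverage_specificity: float
    coverage_quantiles: dict[float, float]
    defective_regions: list[tuple[str, int, int, float]]


def _kept(read: pysam.AlignedSegment, min_mapq: int) -> bool:
    return not (read.is_unmapped or read.is_secondary or read.is_supplementary
                or read.mapping_quality < min_mapq)


def _reference_spans(read: pysam.AlignedSegment) -> list[tuple[int, int]]:
    """Covered reference intervals: M/=/X and D count, N gaps do not."""
    spans = []
    rpos = read.reference_start
    cur_start = None
    for op, length in read.cigartuples or []:
        if op in (0, 2, 7, 8):  # M, D, =, X cover the reference
            if cur_start is None:
                cur_start = rpos
            rpos += length
        elif op == 3:  # N: splice gap, close the span
            if cur_start is not None:
                spans.append((cur_start, rpos))
                cur_start = None
            rpos += length
        # I/S/H/P consume no reference
    if cur_start is not None:
        spans.append((cur_start, rpos))
    return spans


def coverage_track(sam_path: str, min_mapq: int = DEFAULT_MIN_MAPQ,
                   chrom_lengths: dict[str, int] | None = None
                   ) -> CoverageTrack:
    """Per-base depth arrays per chromosome from a sorted SAM.

    Chromosome lengths come from the SAM header unless given explicitly.
    """
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        if chrom_lengths is None:
            chrom_lengths = dict(zip(sam.references, sam.lengths))
        track: CoverageTrack = {
            c: np.zeros(int(n), dtype=np.int64)
            for c, n in chrom_lengths.items()}
        for read in sam:
            if not _kept(read, min_mapq):
                continue
            arr = track[read.reference_name]
            for s, e in _reference_spans(read):
                arr[s:min(e, len(arr))] += 1
    return track


def write_wig(track: CoverageTrack, path: str, name: str = "coverage") -> None:
    """Write the track as UCSC fixedStep WIG (step 1, 1-based starts).

    Zero-depth stretches are omitted; each maximal non-zero run becomes one
    fixedStep block.
    """
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{name}"\n')
        for chrom in sorted(track):
            arr = track[chrom]
            nz = np.flatnonzero(arr)
            if nz.size == 0:
                continue
            # split into maximal consecutive runs
            breaks = np.flatnonzero(np.diff(nz) > 1)
            starts = np.concatenate(([0], breaks + 1))
            ends = np.concatenate((breaks, [nz.size - 1]))
            for si, ei in zip(starts, ends):
                begin = nz[si]
                fh.write(f"fixedStep chrom={chrom} start={begin + 1} step=1\n")
                for v in arr[begin:nz[ei] + 1]:
                    fh.write(f"{v}\n")


def read_wig(path: str, chrom_lengths: dict[str, int]) -> CoverageTrack:
    """Read a fixedStep WIG written by :func:`write_wig`."""
    track = {c: np.zeros(int(n), dtype=np.int64)
             for c, n in chrom_lengths.items()}
    chrom, pos, step = None, 0, 1
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("track"):
                continue
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                chrom = fields["chrom"]
                pos = int(fields["start"]) - 1
                step = int(fields.get("step", 1))
            else:
                track[chrom][pos] = int(line)
                pos += step
    return track


def exon_qc(track: CoverageTrack, index: AnnotationIndex,
            total_mapped_reads: int, on_target_reads: int,
            defective_floor: float = 1.0) -> ExonQCReport:
    """Exome QC from a coverage track and the exon set of the annotation.

    Per-exon average coverage feeds the mean depth on exons (mde), the
    percentage of exons at >= 5x and >= 10x average (inclusive), quantiles
    of the per-exon average (coverage sensitivity) and the list of
    defective exons below ``defective_floor``; specificity is the
    percentage of mapped reads that fall on target exons.
    """
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    exons = index.all_exons()
    if not exons:
        raise ValueError("annotation contains no exons")
    averages = []
    defective = []
    for chrom, s, e in exons:
        arr = track.get(chrom)
        avg = float(arr[s:e].sum()) / (e - s) if arr is not None else 0.0
        averages.append(avg)
        if avg < defective_floor:
            defective.append((chrom, s, e, avg))
    averages = np.asarray(averages)
    qs = {q: float(np.quantile(averages, q))
          for q in (0.0, 0.25, 0.5, 0.75, 1.0)}
    return ExonQCReport(
        mean_depth_exons=float(averages.mean()),
        pct_exons_cov_ge5=float((averages >= 5).mean() * 100),
        pct_exons_cov_ge10=float((averages >= 10).mean() * 100),
        coverage_specificity=on_target_reads / total_mapped_reads * 100,
        coverage_quantiles=qs,
        defective_regions=defective)


def rpkm_quantify(counts: dict[str, int], model_lengths: dict[str, int],
                  total_mapped_reads: int,
                  aligned_bases: dict[str, int] | None = None
                  ) -> list[ExpressionRecord]:
    """Closed-form RPKM for each feature.

    ``aligned_bases`` (bases of kept reads falling on the model) yields the
    mean fold-coverage; absent, mean coverage is reported as 0.
    """
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    records = []
    for feature in counts:
        length = model_lengths[feature]
        if length <= 0:
            raise ValueError(f"zero-length model for {feature}")
        count = counts[feature]
        rpkm = count / (length / 1000.0) / (total_mapped_reads / 1e6)
        mean_cov = (aligned_bases or {}).get(feature, 0) / length
        records.append(ExpressionRecord(feature_id=feature, read_count=count,
                                        mean_coverage=mean_cov, rpkm=rpkm))
    return records


def _feature_trees(index: AnnotationIndex):
    """Interval trees mapping exon pieces to transcript and exon feature ids."""
    trees: dict[str, IntervalTree] = {}
    tx_lengths = {tid: t.length for tid, t in index.transcripts.items()}
    exon_ids = {}
    for chrom, s, e in index.all_exons():
        exon_ids[(chrom, s, e)] = f"{chrom}:{s + 1}-{e}"
    for tid, t in index.transcripts.items():
        tree = trees.setdefault(t.chrom, IntervalTree())
        for s, e in t.exons:
            tree.addi(s, e, (tid, exon_ids[(t.chrom, s, e)]))
    exon_lengths = {fid: e - s for (c, s, e), fid in exon_ids.items()}
    return trees, tx_lengths, exon_lengths


def quantify_sample(sam_path: str, index: AnnotationIndex,
                    min_mapq: int = DEFAULT_MIN_MAPQ
                    ) -> tuple[list[ExpressionRecord], list[ExpressionRecord], int]:
    """Count reads on transcripts and exons and return RPKM records.

    A read is counted once for every transcript (and every exon) whose
    intervals its covered span overlaps.  Returns (transcript records,
    exon records, total mapped reads).
    """
    trees, tx_lengths, exon_lengths = _feature_trees(index)
    tx_counts = {t: 0 for t in tx_lengths}
    tx_bases = {t: 0 for t in tx_lengths}
    ex_counts = {x: 0 for x in exon_lengths}
    ex_bases = {x: 0 for x in exon_lengths}
    total = 0
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        for read in sam:
            if not _kept(read, min_mapq):
                continue
            total += 1
            tree = trees.get(read.reference_name)
            if tree is None:
                continue
            tx_hit: dict[str, int] = {}
            ex_hit: dict[str, int] = {}
            for s, e in _reference_spans(read):
                for iv in tree.overlap(s, e):
                    ol = min(e, iv.end) - max(s, iv.begin)
                    tid, xid = iv.data
                    tx_hit[tid] = tx_hit.get(tid, 0) + ol
                    ex_hit[xid] = ex_hit.get(xid, 0) + ol
            for tid, ol in tx_hit.items():
                tx_counts[tid] += 1
                tx_bases[tid] += ol
            for xid, ol in ex_hit.items():
                ex_counts[xid] += 1
                ex_bases[xid] += ol
    tx_records = rpkm_quantify(tx_counts, tx_lengths, total, tx_bases) \
        if total else []
    ex_records = rpkm_quantify(ex_counts, exon_lengths, total, ex_bases) \
        if total else []
    return tx_records, ex_records, total


def phenotype_matrix(per_sample_records) -> ExpressionMatrix:
    """Aggregate per-sample expression records into a features x samples matrix.

    Accepts a mapping ``sample -> [ExpressionRecord]`` or an iterable of
    ``(sample, records)`` pairs; features missing in a sample are filled
    with count 0 and RPKM 0.  Feature order is sorted, so the result does
    not depend on sample input order.
    """
    if isinstance(per_sample_records, dict):
        pairs = list(per_sample_records.items())
    else:
        pairs = list(per_sample_records)
    seen = [s for s, _ in pairs]
    if len(seen) != len(set(seen)):
        raise ValueError("duplicate sample ids")
    if not pairs:
        raise ValueError("at least one sample required")
    features = sorted({r.feature_id for _, recs in pairs for r in recs})
    rpkm = pd.DataFrame(0.0, index=features, columns=seen)
    counts = pd.DataFrame(0, index=features, columns=seen)
    for sample, recs in pairs:
        for r in recs:
            rpkm.at[r.feature_id, sample] = r.rpkm
            counts.at[r.feature_id, sample] = r.read_count
    return ExpressionMatrix(rpkm=rpkm, counts=counts)


def write_matrix(df: pd.DataFrame, path: str) -> None:
    """Write a features x samples numeric matrix as TSV (feature column first)."""
    df.to_csv(path, sep="\t", index_label="feature")


def read_matrix(path: str) -> pd.DataFrame:
    """Read a matrix written by :func:`write_matrix`."""
    return pd.read_csv(path, sep="\t", index_col="feature").rename_axis(None)
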