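"""Exon-level copy number: log2 probe signals and circular binary segmentation.

Exon RPKM values, normalized against a reference sample (or the mean of a
pool), give per-exon log2-ratio probe signals.  Circular binary
segmentation recursively splits each chromosome's probe sequence at the
arc maximizing the two-sample t statistic between the arc and its
complement, accepting a split only when a permutation test deems it
significant, and emits IGV-compatible ``.seg`` segments with mean probe
signals.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np

from .expression import ExpressionRecord

logger = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_ALPHA = 0.01
DEFAULT_NPERM = 1000


@dataclass
class ProbeSignal:
    """One exon probe: interval plus log2 sample/reference RPKM ratio."""

    chrom: str
    start: int
    end: int
    value: float


@dataclass
class Segment:
    """A constant-copy-number stretch of probes."""

    sample: str
    chrom: str
    start: int
    end: int
    num_probes: int
    segment_mean: float


_FEATURE_RE = re.compile(r"^(?P<chrom>.+):(?P<start>\d+)-(?P<end>\d+)$")


def _feature_interval(feature_id: str) -> tuple[str, int, int]:
    m = _FEATURE_RE.match(feature_id)
    if not m:
        raise ValueError(f"exon feature id not of the form chrom:start-end: "
                         f"{feature_id!r}")
    return m["chrom"], int(m["start"]) - 1, int(m["end"])


def log2_probe_signals(sample_rpkm: list[ExpressionRecord],
                       reference_rpkm: list[ExpressionRecord],
                       pseudocount: float = DEFAULT_PSEUDOCOUNT
                       ) -> list[ProbeSignal]:
    """log2((sample + c) / (reference + c)) per exon, ordered by position.

    Both inputs must cover the same exon set; the pseudocount keeps the
    ratio finite at zero-RPKM exons.
    """
    s_map = {r.feature_id: r.rpkm for r in sample_rpkm}
    r_map = {r.feature_id: r.rpkm for r in reference_rpkm}
    if set(s_map) != set(r_map):
        diff = len(set(s_map) ^ set(r_map))
        raise ValueError(f"sample and reference exon sets differ "
                         f"({diff} features in the symmetric difference)")
    probes = []
    for fid, rpkm in s_map.items():
        chrom, start, end = _feature_interval(fid)
        value = float(np.log2((rpkm + pseudocount)
                              / (r_map[fid] + pseudocount)))
        probes.append(ProbeSignal(chrom=chrom, start=start, end=end,
                                  value=value))
    probes.sort(key=lambda p: (p.chrom, p.start))
    return probes


def pool_reference(rpkm_lists: list[list[ExpressionRecord]]
                   ) -> list[ExpressionRecord]:
    """Per-exon mean RPKM of a pool of samples, on the RPKM scale."""
    if not rpkm_lists:
        raise ValueError("empty reference pool")
    acc: dict[str, list[float]] = {}
    for records in rpkm_lists:
        for r in records:
            acc.setdefault(r.feature_id, []).append(r.rpkm)
    return [ExpressionRecord(feature_id=fid, read_count=0, mean_coverage=0.0,
                             rpkm=float(np.mean(vals)))
            for fid, vals in acc.items()]


# cached per-segment-length geometry of the arc statistic: flattened
# (i, j) pairs of the upper triangle and the 1/n1 + 1/n2 factor
_ARC_CACHE: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}


def _arc_geometry(n: int):
    cached = _ARC_CACHE.get(n)
    if cached is None:
        i, j = np.triu_indices(n + 1, k=1)
        keep = (j - i) <= n - 1  # the full segment is not a split
        i, j = i[keep], j[keep]
        n1 = (j - i).astype(float)
        n2 = n - n1
        inv = 1.0 / n1 + 1.0 / n2
        cached = (i, j, n1, inv)
        if len(_ARC_CACHE) < 64:
            _ARC_CACHE[n] = cached
    return cached


def _arc_t2(S: np.ndarray, q_total: float, n: int) -> np.ndarray:
    """Squared arc-vs-complement t statistic for every arc.

    ``S`` is the prefix-sum vector (length n+1, possibly batched with shape
    (B, n+1)); ``q_total`` the total sum of squares of the segment (batched
    values broadcast).  The pooled within-split sum of squares needs only
    these: ss = sum(x^2) - n1*m1^2 - n2*m2^2.
    """
    i, j, n1, inv = _arc_geometry(n)
    sum1 = S[..., j] - S[..., i]
    total = S[..., -1:]
    m1 = sum1 / n1
    m2 = (total - sum1) / (n - n1)
    diff = m1 - m2
    ss = q_total - n1 * m1 ** 2 - (n - n1) * m2 ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t2 = diff ** 2 / (np.maximum(ss, 0.0) / max(n - 2, 1) * inv)
    t2 = np.where(np.isnan(t2), 0.0, t2)  # 0/0: no contrast at all
    return t2


def _max_arc_t(x: np.ndarray) -> tuple[float, int, int]:
    """Maximal arc t^2 and its (i, j) boundaries; (0, 0, n) if no split."""
    n = x.size
    if n < 3:
        return 0.0, 0, n
    S = np.concatenate(([0.0], np.cumsum(x)))
    t2 = _arc_t2(S, float(np.sum(x * x)), n)
    k = int(np.argmax(t2))
    best = float(t2[k])
    if best <= 0:
        return 0.0, 0, n
    i, j, _, _ = _arc_geometry(n)
    return best, int(i[k]), int(j[k])


def _split_significant(x: np.ndarray, t2_obs: float, alpha: float,
                       n_perm: int, rng: np.random.Generator,
                       batch: int = 64) -> bool:
    """Permutation test of the maximal arc statistic.

    Permutations run in vectorized batches; the test stops early once the
    exceedance count already guarantees p >= alpha.
    """
    if not np.isfinite(t2_obs):
        return True
    n = x.size
    q_total = float(np.sum(x * x))
    exceed = 0
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        perms = rng.permuted(np.broadcast_to(x, (b, n)).copy(), axis=1)
        S = np.concatenate([np.zeros((b, 1)), np.cumsum(perms, axis=1)],
                           axis=1)
        t2 = _arc_t2(S, q_total, n)
        exceed += int((t2.max(axis=1) >= t2_obs).sum())
        done += b
        if (exceed + 1) >= alpha * (n_perm + 1):
            return False
    return (exceed + 1) / (n_perm + 1) < alpha


def _segment_chrom(values: np.ndarray, alpha: float, n_perm: int,
                   rng: np.random.Generator) -> list[tuple[int, int]]:
    """Recursive CBS over one chromosome; returns probe-index intervals."""
    out: list[tuple[int, int]] = []

    def recurse(lo: int, hi: int) -> None:
        x = values[lo:hi]
        t_obs, i, j = _max_arc_t(x)
        if t_obs <= 0 or not _split_significant(x, t_obs, alpha, n_perm, rng):
            out.append((lo, hi))
            return
        cuts = [lo, lo + i, lo + j, hi]
        for a, b in zip(cuts, cuts[1:]):
            if b > a:
                recurse(a, b)

    recurse(0, values.size)
    out.sort()
    return out


def cbs_segment(probes: list[ProbeSignal], alpha: float = DEFAULT_ALPHA,
                n_perm: int = DEFAULT_NPERM, seed: int | None = None,
                sample: str = "sample") -> list[Segment]:
    """Circular binary segmentation of probe signals, per chromosome.

    At each step the arc (i, j] maximizing the pooled two-sample t
    statistic against its complement is tested by permutation (``n_perm``
    draws, seeded); significant splits recurse, so each chromosome is
    partitioned into contiguous segments whose means are the plain
    averages of their member probes.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d gives unstable permutation p-values",
                       n_perm)
    rng = np.random.default_rng(seed)
    by_chrom: dict[str, list[ProbeSignal]] = {}
    for p in probes:
        by_chrom.setdefault(p.chrom, []).append(p)
    segments = []
    for chrom in sorted(by_chrom):
        plist = sorted(by_chrom[chrom], key=lambda p: p.start)
        values = np.array([p.value for p in plist], dtype=float)
        for lo, hi in _segment_chrom(values, alpha, n_perm, rng):
            segments.append(Segment(
                sample=sample, chrom=chrom, start=plist[lo].start,
                end=plist[hi - 1].end, num_probes=hi - lo,
                segment_mean=float(values[lo:hi].mean())))
    return segments


def write_seg(segments: list[Segment], path: str) -> None:
    """Write segments as an IGV ``.seg`` table (1-based inclusive coords)."""
    with open(path, "w") as fh:
        fh.write("Sample\tChromosome\tStart\tEnd\tNum_Probes\tSegment_Mean\n")
        for s in segments:
            fh.write(f"{s.sample}\t{s.chrom}\t{s.start + 1}\t{s.end}\t"
                     f"{s.num_probes}\t{s.segment_mean:.4f}\n")


def read_seg(path: str) -> list[Segment]:
    """Read a ``.seg`` file written by :func:`write_seg`."""
    segments = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("Sample\t"):
            raise ValueError(f"{path}: not a .seg file")
        for line in fh:
            sample, chrom, start, end, n, mean = line.rstrip("\n").split("\t")
            segments.append(Segment(
                sample=sample, chrom=chrom, start=int(start) - 1,
                end=int(end), num_probes=int(n), segment_mean=float(mean)))
    return segments
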