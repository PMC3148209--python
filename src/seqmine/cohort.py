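"""Cross-sample genotype tables, the family-wise filter and trio Mendelian QC.

Genotype categories come from the variant filter: ``het_mut``, ``hom_mut``,
``hom_ref`` and ``qc`` (failed quality control, genotype unknown).  The
family-wise filter drops every position at which at least one family member
is ``qc``.  The remaining rows are checked for Mendelian consistency under
biallelic transmission (hom_ref = RR, het_mut = RA, hom_mut = AA; the child
draws one allele from each parent), and per-sample Mendelian error rates are
reported as an indirect measure of genotyping quality.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import pandas as pd

from .variants import CATEGORIES, GT_HET, GT_HOM, GT_QC, GT_REF, VariantCall

VariantKey = tuple[str, int, str, str]

_ALLELES = {GT_REF: ("R", "R"), GT_HET: ("R", "A"), GT_HOM: ("A", "A")}


@dataclass
class Pedigree:
    """Trio relations: (father, mother, child) sample-id triples."""

    trios: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        for trio in self.trios:
            if len(set(trio)) != 3:
                raise ValueError(f"trio ids not distinct: {trio}")

    @classmethod
    def from_file(cls, path: str) -> "Pedigree":
        """Read a TSV with one ``father mother child`` line per trio."""
        trios = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.split()
                if len(fields) != 3:
                    raise ValueError(f"pedigree line needs 3 ids: {line!r}")
                trios.append(tuple(fields))
        return cls(trios=trios)

    @property
    def samples(self) -> list[str]:
        return [s for trio in self.trios for s in trio]


def aggregate_genotypes(calls_by_sample: dict[str, list[VariantCall]],
                        coverage: dict[str, dict[tuple[str, int], int]] | None = None,
                        cfg=None) -> pd.DataFrame:
    """Union per-sample calls into a positions x samples category matrix.

    Rows are keyed ``(chrom, pos, ref, alt)`` and ordered by (chrom, pos,
    alt).  A sample without a call at a key is re-evaluated from its
    coverage at that position: ``hom_ref`` when the effective depth clears
    the filter's coverage threshold, ``qc`` otherwise (and always ``qc``
    when no coverage information is available).
    """
    from .variants import FilterConfig
    if cfg is None:
        cfg = FilterConfig()
    samples = list(calls_by_sample)
    if len(samples) != len(set(samples)):
        raise ValueError("duplicate sample ids")
    if not samples:
        raise ValueError("at least one sample required")
    keys: set[VariantKey] = set()
    lookup: dict[str, dict[VariantKey, str]] = {}
    for sample, calls in calls_by_sample.items():
        lookup[sample] = {c.key: c.genotype for c in calls}
        keys.update(c.key for c in calls
                    if c.genotype in (GT_HET, GT_HOM))
    ordered = sorted(keys, key=lambda k: (k[0], k[1], k[3]))
    data = {}
    for sample in samples:
        col = []
        depth_map = (coverage or {}).get(sample, {})
        for key in ordered:
            gt = lookup[sample].get(key)
            if gt is None:
                depth = depth_map.get((key[0], key[1]), 0)
                gt = GT_REF if depth >= cfg.min_coverage else GT_QC
            col.append(gt)
        data[sample] = col
    index = pd.MultiIndex.from_tuples(ordered,
                                      names=["chrom", "pos", "ref", "alt"])
    return pd.DataFrame(data, index=index)


def family_filter(matrix: pd.DataFrame, ped: Pedigree) -> pd.DataFrame:
    """Drop rows where any member of any trio is labelled ``qc``."""
    members = [s for s in ped.samples]
    missing = set(members) - set(matrix.columns)
    if missing:
        raise KeyError(f"pedigree samples missing from matrix: {sorted(missing)}")
    mask = (matrix[members] == GT_QC).any(axis=1)
    return matrix.loc[~mask]


def check_trio(father: str, mother: str, child: str) -> str:
    """``consistent`` or ``mendelian_error`` for one category triple.

    The child must be able to draw one allele from each parent; ``qc``
    inputs violate the precondition (apply the family filter first).
    """
    for gt in (father, mother, child):
        if gt == GT_QC:
            raise ValueError("qc genotype: apply the family filter first")
        if gt not in _ALLELES:
            raise ValueError(f"unknown genotype category {gt!r}")
    fa, mo, ch = _ALLELES[father], _ALLELES[mother], _ALLELES[child]
    for a_f, a_m in product(fa, mo):
        if sorted((a_f, a_m)) == sorted(ch):
            return "consistent"
    return "mendelian_error"


def mendelian_error_rate(matrix: pd.DataFrame, ped: Pedigree
                         ) -> pd.DataFrame:
    """Per-sample Mendelian pass/fail counts and error rates.

    For each trio member, rows where that sample carries a mutation
    (``het_mut`` or ``hom_mut``) are split into trio-consistent (passed)
    and inconsistent (failed); rate = failed / (passed + failed), reported
    as NaN when the sample carries no mutations.  Expects the family
    filter to have been applied.
    """
    rows = []
    for father, mother, child in ped.trios:
        verdicts = [
            check_trio(f, m, c)
            for f, m, c in zip(matrix[father], matrix[mother], matrix[child])
        ]
        for sample in (father, mother, child):
            passed = failed = 0
            for gt, verdict in zip(matrix[sample], verdicts):
                if gt in (GT_HET, GT_HOM):
                    if verdict == "consistent":
                        passed += 1
                    else:
                        failed += 1
            total = passed + failed
            rows.append({
                "sample": sample, "passed": passed, "failed": failed,
                "error_rate": failed / total if total else float("nan"),
            })
    return pd.DataFrame(rows).set_index("sample")


def write_genotype_matrix(matrix: pd.DataFrame, path: str) -> None:
    """Write the category matrix as TSV (chrom, pos 1-based, ref, alt, samples)."""
    out = matrix.reset_index()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False)


def read_genotype_matrix(path: str) -> pd.DataFrame:
    """Read a matrix written by :func:`write_genotype_matrix`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df["pos"] = df["pos"].astype(int) - 1
    df = df.set_index(["chrom", "pos", "ref", "alt"])
    bad = set(df.values.ravel()) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown genotype categories in file: {sorted(bad)}")
    return df
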