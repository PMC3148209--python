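"""Synthetic data generators for the whole pipeline.

Three generators emulate the inputs the other modules consume, each a pure
function of its seeded configuration:

* :func:`sim_reads` — a random reference plus coordinate-sorted, pre-aligned
  SAM reads carrying planted SNVs/indels at chosen allele fractions and
  strand balance, with sequencing errors written at reduced Phred quality.
  Alignment itself is out of scope, so simulating the aligner's output is
  the fixture boundary.
* :func:`sim_trio` — father/mother/child genotype categories drawn from a
  minor-allele-frequency distribution with Mendelian transmission, and
  inconsistencies injected at a controlled rate among the child's mutation
  rows (the denominator of the Mendelian error-rate estimator).
* :func:`sim_expression` — a genes x samples expression matrix generated
  from the additive treatment + genotype linear model with Gaussian noise,
  with a tunable treatment-genotype confounding probability (1.0 reproduces
  complete confounding, where every treated sample carries the variant
  allele and no control does).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import pysam

from .association import DesignTable
from .variants import GT_HET, GT_HOM, GT_QC, GT_REF

_BASES = np.array(list("ACGT"))

#: Phred score of a correct base call in simulated reads
GOOD_QUAL = 35
#: Phred score of an injected sequencing error (below the default mask)
ERROR_QUAL = 8


@dataclass
class VariantSpec:
    """A planted variant: position, alternate allele, mixing parameters.

    ``alt`` uses the call encoding: a base for SNVs, ``+SEQ`` for an
    insertion anchored after ``pos``, ``-N`` for a deletion starting at
    ``pos``.  ``allele_fraction`` is the probability a covering read
    carries the variant; ``strand_bias`` the probability a carrier read is
    on the plus strand.
    """

    pos: int
    alt: str
    allele_fraction: float = 0.5
    strand_bias: float = 0.5


@dataclass
class SimConfig:
    """Study conditions of the generators (all randomness from ``seed``)."""

    seed: int = 0
    # read simulation
    reference_length: int = 5000
    read_length: int = 80
    depth: float = 30.0
    base_error_rate: float = 0.001
    variants: list[VariantSpec] = field(default_factory=list)
    chrom: str = "chr1"
    # trio simulation
    n_sites: int = 5000
    maf_low: float = 0.1
    maf_high: float = 0.5
    mendelian_error_rate: float = 0.01
    # expression simulation
    n_genes: int = 200
    n_samples: int = 20
    treatment_effect: float = 2.0
    genotype_effect: float = 2.0
    noise_sd: float = 1.0
    confounding_rho: float = 0.0
    snp_maf: float = 0.3

    def __post_init__(self) -> None:
        for name in ("base_error_rate", "mendelian_error_rate",
                     "confounding_rho", "maf_low", "maf_high", "snp_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.depth <= 0:
            raise ValueError("depth must be positive")


@dataclass
class TruthSet:
    """Ground truth of a simulation, serializable losslessly to JSON."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def write(self, path: str) -> None:
        payload = {"params": self.params, "tables": {}}
        for name, df in self.tables.items():
            payload["tables"][name] = {
                "columns": list(df.columns),
                "data": [list(row) for row in df.itertuples(index=False)],
            }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def read(cls, path: str) -> "TruthSet":
        with open(path) as fh:
            payload = json.load(fh)
        tables = {name: pd.DataFrame(spec["data"], columns=spec["columns"])
                  for name, spec in payload["tables"].items()}
        return cls(tables=tables, params=payload["params"])


# ---------------------------------------------------------------------------
# read-level simulation


def _apply_variants(ref: str, start: int, read_length: int,
                    carried: list[VariantSpec]) -> tuple[str, list] | None:
    """Build (sequence, cigartuples) for a read carrying the given variants.

    SNVs substitute in place; at most one indel is applied per read (the
    leftmost that fits).  Returns None when nothing needs changing.
    """
    seq = list(ref[start:start + read_length])
    cigar = [(0, read_length)]
    indel_done = False
    for v in sorted(carried, key=lambda v: v.pos):
        off = v.pos - start
        if v.alt.startswith("+"):
            if indel_done:
                continue
            ins = v.alt[1:]
            a = off + 1  # bases before the inserted sequence
            c = read_length - a - len(ins)
            if a < 1 or c < 1:
                continue
            seq = list(ref[start:start + a]) + list(ins) + \
                list(ref[start + a:start + a + c])
            cigar = [(0, a), (1, len(ins)), (0, c)]
            indel_done = True
        elif v.alt.startswith("-"):
            if indel_done:
                continue
            dlen = int(v.alt[1:])
            a = off  # matched bases before the deleted span
            b = read_length - a
            if a < 1 or b < 1:
                continue
            seq = list(ref[start:start + a]) + \
                list(ref[start + a + dlen:start + a + dlen + b])
            cigar = [(0, a), (2, dlen), (0, b)]
            indel_done = True
        else:
            if 0 <= off < len(seq) and cigar == [(0, read_length)]:
                seq[off] = v.alt
    return "".join(seq), cigar


def sim_reads(cfg: SimConfig, out_dir: str) -> tuple[str, str, TruthSet]:
    """Write a reference FASTA and sorted SAM with planted variants.

    Returns (fasta_path, sam_path, truth).  Reads tile the reference
    uniformly at the configured depth; carrier status at each planted
    variant is an independent Bernoulli draw at its allele fraction, with
    carrier strand drawn at the variant's strand bias.  Sequencing errors
    are substituted at ``base_error_rate`` and written at Phred
    {ERROR_QUAL}; correct calls carry Phred {GOOD_QUAL}.
    """
    import os

    rng = np.random.default_rng(cfg.seed)
    L, rl = cfg.reference_length, cfg.read_length
    ref_arr = rng.choice(_BASES, size=L)
    # a planted SNV must differ from the reference: nudge the reference
    # base when the random draw collides with the requested alt allele
    for v in cfg.variants:
        if not v.alt.startswith(("+", "-")) and ref_arr[v.pos] == v.alt:
            ref_arr[v.pos] = next(b for b in "ACGT" if b != v.alt)
    ref = "".join(ref_arr)
    # overlapping planted indels are ambiguous to apply
    spans = []
    for v in cfg.variants:
        if v.alt.startswith("-"):
            spans.append((v.pos, v.pos + int(v.alt[1:])))
        elif v.alt.startswith("+"):
            spans.append((v.pos, v.pos + 1))
    spans.sort()
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError("overlapping planted indels")

    n_reads = int(round(cfg.depth * L / rl))
    starts = np.sort(rng.integers(0, max(1, L - rl + 1), size=n_reads))
    fasta_path = os.path.join(out_dir, "reference.fa")
    with open(fasta_path, "w") as fh:
        fh.write(f">{cfg.chrom}\n")
        for i in range(0, L, 60):
            fh.write(ref[i:i + 60] + "\n")

    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": cfg.chrom, "LN": L}]}
    sam_path = os.path.join(out_dir, "reads.sam")
    truth_rows = []
    for v in cfg.variants:
        ref_allele = ref[v.pos] if not v.alt.startswith(("+", "-")) else \
            ref[v.pos]
        truth_rows.append({"pos": v.pos, "ref": ref_allele, "alt": v.alt,
                           "allele_fraction": v.allele_fraction,
                           "strand_bias": v.strand_bias})
    with pysam.AlignmentFile(sam_path, "w", header=header) as sam:
        for idx, start in enumerate(starts):
            start = int(start)
            carried = []
            for v in cfg.variants:
                covers = start <= v.pos < start + rl
                if covers and rng.random() < v.allele_fraction:
                    carried.append(v)
            if carried:
                strand_plus = rng.random() < carried[0].strand_bias
            else:
                strand_plus = rng.random() < 0.5
            seq, cigar = _apply_variants(ref, start, rl, carried)
            seq = list(seq)
            quals = np.full(len(seq), GOOD_QUAL, dtype=np.int32)
            errs = rng.random(len(seq)) < cfg.base_error_rate
            for k in np.flatnonzero(errs):
                others = [b for b in "ACGT" if b != seq[k]]
                seq[k] = others[int(rng.integers(3))]
                quals[k] = ERROR_QUAL
            a = pysam.AlignedSegment(header=pysam.AlignmentHeader.from_dict(header))
            a.query_name = f"read{idx:06d}"
            a.query_sequence = "".join(seq)
            a.flag = 0 if strand_plus else 16
            a.reference_id = 0
            a.reference_start = start
            a.mapping_quality = 60
            a.cigartuples = cigar
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in quals))
            sam.write(a)
    truth = TruthSet(
        tables={"variants": pd.DataFrame(
            truth_rows, columns=["pos", "ref", "alt", "allele_fraction",
                                 "strand_bias"])},
        params={"seed": cfg.seed, "reference_length": L,
                "read_length": rl, "depth": cfg.depth,
                "base_error_rate": cfg.base_error_rate,
                "chrom": cfg.chrom})
    return fasta_path, sam_path, truth


# ---------------------------------------------------------------------------
# trio simulation

_CAT_FROM_DOSE = {0: GT_REF, 1: GT_HET, 2: GT_HOM}
_ALLELES = {GT_REF: ("R", "R"), GT_HET: ("R", "A"), GT_HOM: ("A", "A")}


def _consistent(father: str, mother: str, child: str) -> bool:
    fa, mo, ch = _ALLELES[father], _ALLELES[mother], _ALLELES[child]
    return any(sorted((x, y)) == sorted(ch) for x in fa for y in mo)


def _inconsistent_mutated(father: str, mother: str) -> list[str]:
    return [c for c in (GT_HET, GT_HOM)
            if not _consistent(father, mother, c)]


def sim_trio(cfg: SimConfig) -> tuple[pd.DataFrame, TruthSet]:
    """Simulate trio genotype categories with injected Mendelian errors.

    Parental genotypes are Hardy-Weinberg draws at a per-site minor allele
    frequency uniform on [maf_low, maf_high]; the child inherits one allele
    from each parent.  Whenever the child carries a mutation, with
    probability ``mendelian_error_rate`` its genotype is replaced by a
    uniformly chosen *inconsistent mutated* genotype (sites where no such
    replacement exists are redrawn), so the injected rate is a Bernoulli
    rate within the child's mutation rows — the denominator of the
    error-rate estimator.  Sites with no mutation in the family are
    redrawn.  Returns the three-column category matrix and the per-site
    truth labels.
    """
    rng = np.random.default_rng(cfg.seed)

    def draw_trio() -> tuple[float, str, str, str]:
        maf = rng.uniform(cfg.maf_low, cfg.maf_high)
        father = _CAT_FROM_DOSE[int(rng.binomial(2, maf))]
        mother = _CAT_FROM_DOSE[int(rng.binomial(2, maf))]
        fa = _ALLELES[father][int(rng.integers(2))]
        mo = _ALLELES[mother][int(rng.integers(2))]
        child = _CAT_FROM_DOSE[(fa == "A") + (mo == "A")]
        return maf, father, mother, child

    rows, truth_rows = [], []
    while len(rows) < cfg.n_sites:
        maf, father, mother, child = draw_trio()
        if father == mother == child == GT_REF:
            continue  # uninformative row: nobody carries a mutation
        injected = False
        if child in (GT_HET, GT_HOM) and \
                rng.random() < cfg.mendelian_error_rate:
            # redraw conditioned on an injectable configuration so the
            # error stays a Bernoulli event within child-mutation rows
            options = _inconsistent_mutated(father, mother)
            while not options or child == GT_REF:
                maf, father, mother, child = draw_trio()
                options = _inconsistent_mutated(father, mother)
            child = options[int(rng.integers(len(options)))]
            injected = True
        rows.append((father, mother, child))
        truth_rows.append({"maf": maf, "injected": injected,
                           "consistent": _consistent(father, mother, child)})
    n = len(rows)
    matrix = pd.DataFrame(rows, columns=["father", "mother", "child"],
                          index=pd.MultiIndex.from_tuples(
                              [("chr1", i * 10, "A", "G") for i in range(n)],
                              names=["chrom", "pos", "ref", "alt"]))
    truth = TruthSet(tables={"sites": pd.DataFrame(truth_rows)},
                     params={"seed": cfg.seed, "n_sites": cfg.n_sites,
                             "mendelian_error_rate": cfg.mendelian_error_rate})
    return matrix, truth


# ---------------------------------------------------------------------------
# expression simulation


def sim_expression(cfg: SimConfig
                   ) -> tuple[pd.DataFrame, DesignTable, pd.DataFrame, TruthSet]:
    """Simulate expression with treatment effects confounded by genotype.

    One SNP per gene.  With probability ``confounding_rho`` a gene's SNP
    is completely confounded with treatment (treated samples homozygous
    for the alternate allele, controls homozygous reference); otherwise
    its codes are independent Hardy-Weinberg draws at ``snp_maf``.  Expression follows the additive linear model
    ``b0 + treatment_effect*tr + genotype_effect*snp + N(0, noise_sd)``
    (effects in units of the noise SD).  Returns (expression genes x
    samples, design, genotype codes SNPs x samples, truth).
    """
    if cfg.n_samples < 6:
        raise ValueError("need at least 6 samples")
    rng = np.random.default_rng(cfg.seed)
    samples = [f"s{i:03d}" for i in range(cfg.n_samples)]
    half = cfg.n_samples // 2
    treatment = pd.Series(
        ["control"] * half + ["treated"] * (cfg.n_samples - half),
        index=samples)
    tr = (treatment == "treated").to_numpy().astype(float)
    genes = [f"gene{i:04d}" for i in range(cfg.n_genes)]
    expr = np.empty((cfg.n_genes, cfg.n_samples))
    geno = np.empty((cfg.n_genes, cfg.n_samples))
    truth_rows = []
    for g in range(cfg.n_genes):
        confounded = rng.random() < cfg.confounding_rho
        if confounded:
            snp = 2.0 * tr  # treated hom-alt, controls hom-ref
        else:
            snp = rng.binomial(2, cfg.snp_maf, size=cfg.n_samples).astype(float)
        noise = rng.normal(0.0, cfg.noise_sd, size=cfg.n_samples)
        expr[g] = (10.0 + cfg.treatment_effect * cfg.noise_sd * tr
                   + cfg.genotype_effect * cfg.noise_sd * snp + noise)
        geno[g] = snp
        truth_rows.append({
            "gene": genes[g], "confounded": confounded,
            "beta_treatment": cfg.treatment_effect * cfg.noise_sd,
            "beta_genotype": cfg.genotype_effect * cfg.noise_sd})
    expr_df = pd.DataFrame(expr, index=genes, columns=samples)
    geno_df = pd.DataFrame(geno, index=[f"{g}_snp" for g in genes],
                           columns=samples)
    design = DesignTable(treatment=treatment, genotypes=geno_df)
    truth = TruthSet(tables={"genes": pd.DataFrame(truth_rows)},
                     params={k: v for k, v in asdict(cfg).items()
                             if not isinstance(v, list)})
    return expr_df, design, geno_df, truth
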