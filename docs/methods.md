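# Methods

This note documents the models and procedures implemented in seqmine, the
parameter choices behind them, what the synthetic-data generators do and do
not emulate, and the numerical decisions a maintainer should know about.

## Coordinates and alleles

All internal coordinates are 0-based half-open. GTF and VCF inputs
(1-based inclusive) and SAM positions are converted at the parsing
boundary; BED12 already matches. Display output (pileup TSV, genotype
matrices, `.seg`) is 1-based. Alternate alleles are encoded as a single
base for substitutions, `+SEQ` for an insertion anchored after the
position, and `-N` for a deletion of N bases starting at the position.

## Pileup

`pileup_from_sam` streams a coordinate-sorted SAM (via pysam) against the
reference FASTA and emits per-position columns of strand-resolved base
observations with Phred scores, plus insertion and deletion evidence.
CIGAR semantics: M/=/X contribute base evidence; I records the inserted
sequence at the preceding aligned column (the convention of standard
pileup formats); D records the deletion length at its first deleted
position and contributes no base evidence inside the deleted span; S/H/N/P
contribute nothing. Reads that are unmapped, secondary or supplementary,
or below the mapping-quality cutoff (default 10, applied inclusively as
mapq ≥ 10) are excluded. Duplicate reads are *not* removed. The reference
is required so that every column carries its reference base, which fixes
ref/alt polarity for the filter and annotation.

## The variant filter

Quality masking runs first: base calls with Phred < `min_base_qual`
(default 10) are removed from all tallies; observations without a quality
string are kept (masking applies only when qualities are present), and
indel evidence carries no base quality, so it is unaffected. The
*effective coverage* is the masked base evidence plus reads whose deletion
starts at the position — such reads cover the site without contributing a
base call, and including them makes the deletion-allele fraction well
defined.

The candidate alternate allele is the highest-count non-reference
evidence after masking; ties break lexicographically with bases before
indel alleles (A < C < G < T < indel). The paper-facing thresholds are all
inclusive minima: effective coverage ≥ 20; minor strand frequency of the
**alternate-supporting** reads ≥ 0.1; alternate fraction ≥ 0.25. The
strand criterion is computed on supporting reads rather than all covering
reads because supporting-read strand imbalance is the standard
strand-artifact signal; this is a declared reading of an ambiguous
description. Indels pass through the same four criteria with the
insertion sequence or deletion length as the allele.

Genotype categories: a passing candidate is `hom_mut` when the alternate
fraction reaches `hom_alt_freq` (default 0.75, configurable — the het/hom
boundary is a declared default, not an inherited constant), otherwise
`het_mut`; a failing candidate is `qc`; a non-candidate position is
`hom_ref` or `qc` depending on whether its effective coverage clears the
same coverage threshold.

A note on monotonicity: raising the *decision* thresholds (coverage,
strand, alternate fraction) can only shrink the passing set, and the test
suite asserts this. No such guarantee holds for the base-quality cutoff:
because masking removes low-quality *reference* calls too, a stricter
quality cutoff can raise the alternate fraction and turn a failing site
into a passing one. That is a property of the masking semantics, not a
defect.

## Annotation

Transcript models come from GTF (exon/CDS features grouped by
`transcript_id`) or BED12 (blocks as exons, thickStart/thickEnd as CDS)
into per-chromosome interval trees. Region categories: upstream/downstream
within a configurable flank (default 1000 bp, oriented by strand), 5'/3'
UTR, coding exon, intron, splice site, noncoding exon, intergenic (no
overlap). The splice-site window is 2 intronic bases at each exon
boundary — the canonical donor/acceptor definition; the flank size and
splice window are declared defaults, as the category names alone do not
fix them. A variant overlapping several transcripts is annotated once per
transcript.

Coding consequences translate the affected codon through the standard
genetic code: synonymous, missense, nonsense for substitutions; frameshift
for indels whose length is not a multiple of 3, in-frame indel otherwise;
codon number = floor(CDS offset / 3) + 1. On minus-strand transcripts the
alleles are reverse-complemented before codon lookup. Consequence calling
requires the CDS length to be a multiple of 3; models violating this are
annotated at region level only.

## Cohort genotyping and trio QC

Variants are keyed `(chrom, pos, ref, alt)` — the same position with two
alternate alleles is two rows. Aggregation takes the union of keys over
samples; a sample without a call at a key is re-evaluated from its
coverage at that position (`hom_ref` if ≥ the coverage threshold, else
`qc`). The family filter removes every row in which any trio member is
`qc`.

Mendelian checking maps categories to biallelic genotypes (RR/RA/AA) and
asks whether the child's pair can be drawn one allele from each parent;
the check is symmetric in the parents. Per-sample error rates count only
rows where that sample carries a mutation: rate = failed/(passed+failed),
undefined (NaN) when a sample carries none. The per-sample denominator is
a declared choice; the alternative f/p definition differs only in the
third decimal at realistic error rates.

## Expression

Coverage tracks count M/=/X and D spans (an exome deletion still
represents locally sequenced DNA) but not N gaps (RNA splice gaps are not
coverage). Exome QC reports the mean per-exon average depth, the
percentage of exons at average ≥ 5× and ≥ 10× (inclusive), quantiles of
the per-exon average, on-target specificity (reads on exons / mapped
reads), and exons below a defective floor (default average < 1×).

RPKM = count / (model length / 1000) / (total mapped reads / 10⁶), with
"total mapped reads" the reads passing the mapq filter in that sample. A
read is counted once for every transcript (and every exon) whose exon
intervals its covered span overlaps; there is no multi-mapping rescue or
fractional apportionment. Mean fold-coverage of a model is the aligned
bases falling on it divided by its length. Exon features are identified by
their interval (`chrom:start-end`, 1-based), which makes exon-level
records directly usable as CNV probes.

WIG output is fixedStep, step 1, 1-based starts, one block per maximal
non-zero run; the reader reconstructs a track exactly given chromosome
lengths.

## DEG, genotype-controlled DEG, variance components

The two-group test per feature is an equal-variance Student's t plus a
Mann-Whitney rank-sum test, with Benjamini-Hochberg FDR across features on
the t p-values. Fold change is log2 of group-mean RPKM with a 0.5
pseudocount to tolerate zeros.

The genotype-controlled procedure fits both models by ordinary least
squares. The controlled model is a fixed-effects linear model with the
gene's SNP codes (additive 0/1/2; the coding is a declared choice) as
covariates; this follows the model equations as written rather than a
mixed-effects formulation, and it requires n ≥ m + 3 samples for m SNP
covariates. Aliased SNP columns are dropped by greedy rank selection;
if the treatment itself adds no rank over the genotype block (complete
confounding), the controlled p-value is reported as 1.0 — "no longer
significant" — rather than raising an error. With m = 0 the controlled
test reduces exactly to the uncontrolled one.

Variance components use a sequential sum-of-squares decomposition of the
controlled fit with the genotype block entered first, then treatment,
normalized by the total sum of squares; the residual is the remainder.
REML-based mixed-model components were deliberately not used: the
sequential decomposition is exact for the fixed-effects model actually
fitted, and reproduces the qualitative contrast of interest (controlled
gene lists show lower residual and higher genotype fractions than naive
lists). Zero-variance rows return all-zero components with a warning.

## eQTL

Each (gene, SNP) pair is a simple linear regression of expression on the
additive genotype code; unknown genotypes (`qc`) are excluded pairwise;
monomorphic SNPs are skipped and logged. Bonferroni adjustment multiplies
by the number of tests actually performed in the scan. A SNP is cis to a
gene when it lies within the gene span ± a window (default 1 Mb,
configurable); anything else, including other chromosomes, is trans.

## Pathway-distance association

Pathways reduce to directed gene-gene edge lists and merge by set union.
All-pairs shortest-path lengths are computed with Johnson's algorithm
(networkx), which on unit weights is equivalent to per-source BFS — the
test suite asserts exact equality against a BFS oracle. Unreachable pairs
are set to N (the gene count). The p-value counts ordered pairs with
distance ≤ the observed one over all N² pairs, diagonal included; the
diagonal is included deliberately so the cis case (distance 0) has a
well-defined, non-zero and minimal p-value, and ties count as at least as
extreme. The N² background is isolated behind a single constant
(`INCLUDE_DIAGONAL`).

## CNV

Probe signals are log2((sample RPKM + c)/(reference RPKM + c)) per exon
with pseudocount c = 0.5 (zero-RPKM exons would otherwise be ±∞); the
reference is either a matched sample or the per-exon mean RPKM of a pool
(averaged on the RPKM scale before the log). Only exon probes are
emitted — intronic or intergenic calls are not meaningful from capture
data.

Segmentation is a direct CBS implementation: for each segment, the arc
(i, j] maximizing the pooled two-sample t statistic against its complement
(computed from prefix sums; the pooled within-split sum of squares needs
only the global sum of squares and the arc sum) is tested by permutation —
default 1000 permutations, p = (exceedances+1)/(n_perm+1), accepted when
p < α = 0.01 — and accepted splits recurse. Permutations run in
vectorized batches with early stopping once the exceedance count already
guarantees p ≥ α. The pruning/"undo" refinements of the full published
CBS are deliberately omitted — a declared simplification adequate at exon
scale, validated by breakpoint-recovery simulations (a 1.0 step in σ = 0.3
noise over 200 probes is located within ±2 probes in ≥ 95% of seeded
runs). Degenerate inputs: constant segments have no valid split (the
statistic is 0/0, mapped to 0) and remain whole; segments of fewer than 3
probes are never split. `.seg` output is the standard six-column IGV
table, 1-based inclusive, means printed to 4 decimals.

## Synthetic data

The generators are pure functions of a seeded configuration and emulate
the *shape* of real inputs, not their full error structure.

- `sim_reads` writes a random reference and coordinate-sorted SAM reads
  (default 80 bp, the common read length of the platform generation this
  toolkit targets; default depth 30×) tiling it uniformly. Carrier status
  at each planted variant is Bernoulli at its allele fraction; carrier
  strand is Bernoulli at its strand bias; sequencing errors are base
  substitutions at rate 0.001 written at Phred 8 (below the default mask)
  against Phred 35 for correct calls. The reference base at a planted SNV
  is forced to differ from the alt allele. Reads are generated pre-aligned
  because alignment is outside the toolkit's scope — the fixture boundary
  is the aligner's output. Not emulated: PCR duplicates, indel-containing
  error processes, platform-specific quality profiles, paired-end
  structure.
- `sim_trio` draws parental genotypes from Hardy-Weinberg at per-site
  minor-allele frequencies uniform on [0.1, 0.5] and transmits one allele
  from each parent. With probability `mendelian_error_rate`, a site where
  the child carries a mutation has the child replaced by a uniformly
  chosen *inconsistent mutated* genotype (redrawing the site if no such
  genotype exists for the parental pair), which makes the injected rate a
  Bernoulli rate within exactly the rows the error-rate estimator counts.
  Uninformative all-reference rows are redrawn.
- `sim_expression` generates e = β₀ + β_tr·tr + β_snp·SNP + N(0, σ) per
  gene with one within-gene SNP, defaults n = 20 samples and effects of
  2σ. With probability `confounding_rho` the SNP is completely confounded
  with treatment (treated samples homozygous alternate, controls
  homozygous reference); otherwise codes are Hardy-Weinberg draws at MAF
  0.3. Gaussian noise on the (log-scale) expression matches the additive
  error assumption of the linear models.

Because the generators match the models' own assumptions, passing tests
demonstrate correctness of the implementations and the internal
consistency of the pipeline — not robustness to the ways real data
violate those assumptions (overdispersed counts, capture bias, batch
effects, alignment artifacts).

## Problem sizes used in validation

The validation suite and the reproduction script use desk-scale problem
sizes chosen to give statistically decisive checks: 10,000 random pileup
columns against the brute-force filter oracle; 5,000–10,000 trio sites at
1–2% injected error; 1,000 random datasets for the slope/t identity
(agreement to 1e-10); 200 replicates for confounding exclusion and power;
100 random digraphs (N ≤ 50) for the BFS equivalence; 100 seeded CBS runs
of 200 probes; and 100 null eQTL scans of 1,000 tests each. The null
family-wise error check accepts counts up to the one-sided 95% binomial
bound for the nominal 0.05 rate, which is the statistically correct test
of "rate ≤ nominal" (the measured rate over 400 replicates is 0.0475).

## Known limitations

- Rule-based genotyping: no genotype likelihoods, no joint calling across
  samples; somatic use means lowering the alternate-fraction threshold.
- Read counting is overlap-based; isoform deconvolution, junction
  discovery and TPM-style normalizations are out of scope.
- The eQTL scan is single-marker OLS without population-structure or
  kinship correction.
- CBS lacks the pruning/undo steps of the full published algorithm and
  does not call absolute integer copy numbers.
- BAM/CRAM are not parsed (convert to SAM text first); KEGG access and
  annotation downloads are out of scope — inputs are generic
  GTF/BED12/VCF/edge-list files.
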