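"""Differential expression, genotype-controlled DEG and eQTL scanning.

Differential expression between two treatment groups is tested per feature
with an equal-variance Student's t-test and a Wilcoxon rank-sum test, with
Benjamini-Hochberg FDR across features.

The genotype-controlled procedure fits two nested linear models per gene:

    e_i = b0 + b  * tr_i + eps_i                         (uncontrolled)
    e_i = b0 + b' * tr_i + sum_j bj * SNP_ij + eps_i     (controlled)

where ``tr_i`` is the treatment group of sample i and ``SNP_ij`` the
additive 0/1/2 genotype code of the j-th SNP in the gene region for sample
i.  The slope test of the first model is numerically the pooled-variance
two-group t-test; a genotype-controlled DEG must be significant in both the
uncontrolled slope test and the controlled ``b'`` test.  When treatment is
perfectly confounded with the genotype covariates (aliased design) the
controlled test is reported as non-significant (p = 1) rather than as an
error.

eQTLs are scanned as per-(gene, SNP) simple regressions of expression on
the additive genotype code, Bonferroni-adjusted over the number of tests
actually performed; a SNP within the gene span +/- a window (default 1 Mb)
is cis, anything else trans.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.01
DEFAULT_CIS_WINDOW = 1_000_000
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class DesignTable:
    """Sample design: treatment assignment and optional genotype codes.

    ``treatment`` maps sample id to group label; ``genotypes`` is a
    SNPs x samples frame of additive codes in {0, 1, 2} (NaN = unknown).
    """

    treatment: pd.Series
    genotypes: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.treatment = pd.Series(self.treatment)
        if self.genotypes is not None:
            vals = self.genotypes.values
            ok = np.isin(vals[~pd.isna(vals)], (0, 1, 2))
            if not ok.all():
                raise ValueError("genotype codes must be 0, 1 or 2")

    @property
    def samples(self) -> list[str]:
        return list(self.treatment.index)

    @property
    def groups(self) -> list[str]:
        return sorted(self.treatment.unique())

    def treatment_codes(self) -> np.ndarray:
        """0/1 codes for a two-group design (groups in sorted label order)."""
        groups = self.groups
        if len(groups) != 2:
            raise ValueError(f"exactly 2 treatment groups required, "
                             f"got {groups}")
        return (self.treatment == groups[1]).to_numpy().astype(float)


@dataclass
class GCDEGResult:
    """Outcome of the genotype-controlled test for one gene."""

    feature: str
    p_unadjusted: float
    p_adjusted: float
    is_gcdeg: bool
    variance_components: tuple[float, float, float]  # treatment, genotype, residual


def _safe_p(p: float) -> float:
    return 1.0 if (p is None or np.isnan(p)) else float(p)


def deg_test(expr: pd.DataFrame, design: DesignTable,
             pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Two-group differential expression over a features x samples frame.

    Returns a frame indexed by feature with ``log2_fold_change`` (second
    sorted group over first, with a pseudocount), ``t_pvalue`` (pooled
    variance), ``wilcoxon_pvalue`` and BH ``fdr`` on the t p-values.
    """
    groups = design.groups
    if len(groups) != 2:
        raise ValueError("exactly 2 treatment groups required")
    s1 = [s for s in design.samples if design.treatment[s] == groups[0]]
    s2 = [s for s in design.samples if design.treatment[s] == groups[1]]
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError("each treatment group needs at least 2 samples")
    a = expr[s1].to_numpy(dtype=float)
    b = expr[s2].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t_res = stats.ttest_ind(b, a, axis=1, equal_var=True)
        t_p = np.where(np.isnan(t_res.pvalue), 1.0, t_res.pvalue)
        w_p = np.array([
            _safe_p(stats.mannwhitneyu(rb, ra, alternative="two-sided").pvalue)
            if not np.array_equal(ra, rb) else 1.0
            for ra, rb in zip(a, b)])
    with np.errstate(invalid="ignore", divide="ignore"):
        lfc = np.log2((b.mean(axis=1) + pseudocount) /
                      (a.mean(axis=1) + pseudocount))
    fdr = multipletests(t_p, method="fdr_bh")[1]
    return pd.DataFrame({
        "log2_fold_change": lfc, "t_pvalue": t_p,
        "wilcoxon_pvalue": w_p, "fdr": fdr}, index=expr.index)


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float, int]:
    """Least squares fit returning (coef, RSS, rank)."""
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ coef) ** 2))
    return coef, rss, rank


def _slope_pvalue(y: np.ndarray, X: np.ndarray, col: int) -> float:
    """Two-sided t-test p-value of one coefficient of an OLS fit."""
    n, k = X.shape
    coef, rss, rank = _ols(y, X)
    df = n - rank
    if df <= 0:
        return 1.0
    sigma2 = rss / df
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(sigma2 * XtX_inv[col, col])
    if se == 0:
        return 0.0 if coef[col] != 0 else 1.0
    t = coef[col] / se
    return float(2 * stats.t.sf(abs(t), df))


def _independent_columns(base: np.ndarray, candidates: np.ndarray
                         ) -> list[int]:
    """Indices of candidate columns that extend the column space of base."""
    kept: list[int] = []
    cur = base
    rank = np.linalg.matrix_rank(cur)
    for j in range(candidates.shape[1]):
        trial = np.column_stack([cur, candidates[:, j]])
        r = np.linalg.matrix_rank(trial)
        if r > rank:
            kept.append(j)
            cur, rank = trial, r
    return kept


def gcdeg_test(expr_row: np.ndarray, design: DesignTable,
               snps_in_gene: np.ndarray | pd.DataFrame | None = None,
               alpha: float = DEFAULT_ALPHA,
               feature: str = "") -> GCDEGResult:
    """Uncontrolled and genotype-controlled treatment tests for one gene.

    ``snps_in_gene`` holds the gene's SNP codes, one column per SNP, one
    row per sample (``None`` or zero columns reduces the controlled model
    to the uncontrolled one).  Aliased SNP columns are dropped; if the
    treatment itself is aliased with the genotype block, the controlled
    p-value is 1.0.
    """
    y = np.asarray(expr_row, dtype=float)
    tr = design.treatment_codes()
    n = y.size
    if snps_in_gene is None:
        S = np.empty((n, 0))
    else:
        S = np.asarray(snps_in_gene, dtype=float)
        if S.ndim == 1:
            S = S[:, None]
    m = S.shape[1]
    if m > 0 and m + 2 >= n:
        raise ValueError(f"too many SNP covariates ({m}) for {n} samples; "
                         "need n >= m + 3")
    ones = np.ones((n, 1))
    X1 = np.column_stack([ones, tr])
    p_un = _slope_pvalue(y, X1, col=1)
    kept = _independent_columns(ones, S) if m else []
    S_kept = S[:, kept]
    base = np.column_stack([ones, S_kept])
    if np.linalg.matrix_rank(np.column_stack([base, tr])) == \
            np.linalg.matrix_rank(base):
        p_adj = 1.0  # treatment fully confounded with genotype
        rss_g = _ols(y, base)[1]
        rss_full = rss_g
    else:
        X2 = np.column_stack([base, tr])
        p_adj = _slope_pvalue(y, X2, col=X2.shape[1] - 1)
        rss_g = _ols(y, base)[1]
        rss_full = _ols(y, X2)[1]
    total_ss = float(np.sum((y - y.mean()) ** 2))
    if total_ss == 0:
        logger.warning("zero total variance for %s", feature or "feature")
        vc = (0.0, 0.0, 0.0)
    else:
        rss0 = total_ss
        geno = (rss0 - rss_g) / total_ss
        treat = (rss_g - rss_full) / total_ss
        vc = (treat, geno, rss_full / total_ss)
    return GCDEGResult(feature=feature, p_unadjusted=p_un, p_adjusted=p_adj,
                       is_gcdeg=(p_un < alpha and p_adj < alpha),
                       variance_components=vc)


def variance_components(expr_row: np.ndarray, design: DesignTable,
                        snps_in_gene=None) -> tuple[float, float, float]:
    """(treatment, genotype, residual) variance fractions for one gene.

    Sequential sum-of-squares decomposition of the controlled fit, genotype
    block entered first, normalized by the total sum of squares.
    """
    return gcdeg_test(expr_row, design, snps_in_gene).variance_components


def gcdeg_scan(expr: pd.DataFrame, design: DesignTable,
               gene_snps: dict[str, list[str]] | None = None,
               alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Run the genotype-controlled test over every feature of a matrix.

    ``gene_snps`` maps a feature to the SNP ids (rows of
    ``design.genotypes``) inside its gene region; features without SNPs are
    tested uncontrolled on both sides.
    """
    rows = []
    for feature in expr.index:
        snp_ids = (gene_snps or {}).get(feature, [])
        S = None
        if snp_ids and design.genotypes is not None:
            S = design.genotypes.loc[snp_ids, expr.columns].T.to_numpy()
        res = gcdeg_test(expr.loc[feature].to_numpy(), design, S,
                         alpha=alpha, feature=feature)
        treat, geno, resid = res.variance_components
        rows.append({
            "feature": feature, "p_unadjusted": res.p_unadjusted,
            "p_adjusted": res.p_adjusted, "is_gcdeg": res.is_gcdeg,
            "vc_treatment": treat, "vc_genotype": geno, "vc_residual": resid})
    return pd.DataFrame(rows).set_index("feature")


def code_genotype_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Convert a category matrix to additive codes (qc -> NaN).

    Rows keep the (chrom, pos, ref, alt) index; values are 0 (hom_ref),
    1 (het_mut), 2 (hom_mut).
    """
    mapping = {"hom_ref": 0.0, "het_mut": 1.0, "hom_mut": 2.0,
               "qc": np.nan}
    return matrix.apply(lambda c: c.map(mapping))


def eqtl_scan(expr: pd.DataFrame, genotypes: pd.DataFrame,
              gene_loci: dict[str, tuple[str, int, int]],
              snp_loci: dict[str, tuple[str, int]],
              mode: str = "both",
              cis_window: int = DEFAULT_CIS_WINDOW) -> pd.DataFrame:
    """Scan all (gene, SNP) pairs for expression-genotype association.

    ``expr`` is genes x samples, ``genotypes`` SNPs x samples with additive
    codes (NaN excluded pairwise).  Returns one row per test with slope,
    p-value, Bonferroni-adjusted p-value (over tests performed) and the
    cis/trans relation.
    """
    if mode not in ("cis", "trans", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    shared = [s for s in expr.columns if s in genotypes.columns]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    expr_np = expr[shared].to_numpy(dtype=float)
    geno_np = genotypes[shared].to_numpy(dtype=float)
    snp_ids = list(genotypes.index)
    rows = []
    for gi, gene in enumerate(expr.index):
        g_chrom, g_start, g_end = gene_loci[gene]
        y_all = expr_np[gi]
        for si, snp in enumerate(snp_ids):
            s_chrom, s_pos = snp_loci[snp]
            cis = (s_chrom == g_chrom
                   and g_start - cis_window <= s_pos < g_end + cis_window)
            relation = "cis" if cis else "trans"
            if mode == "cis" and not cis:
                continue
            if mode == "trans" and cis:
                continue
            x_all = geno_np[si]
            keep = ~np.isnan(x_all) & ~np.isnan(y_all)
            x, y = x_all[keep], y_all[keep]
            if x.size < 3 or np.all(x == x[0]):
                logger.info("skipping monomorphic/underpowered SNP %s", snp)
                continue
            if np.all(y == y[0]):
                beta, p = 0.0, 1.0
            else:
                res = stats.linregress(x, y)
                beta, p = float(res.slope), _safe_p(res.pvalue)
            rows.append({"gene": gene, "snp": snp, "beta": beta,
                         "pvalue": p, "relation": relation,
                         "n": int(x.size)})
    out = pd.DataFrame(rows,
                       columns=["gene", "snp", "beta", "pvalue",
                                "relation", "n"])
    m = len(out)
    out["adjusted_pvalue"] = np.minimum(1.0, out["pvalue"] * m) if m else []
    return out
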