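"""DEG testing, genotype-controlled DEG, variance components and eQTL."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seqmine.association import (DesignTable, code_genotype_matrix, deg_test,
                                 eqtl_scan, gcdeg_scan, gcdeg_test,
                                 variance_components)
from seqmine.simdata import SimConfig, sim_expression


def design_of(n1=4, n2=4):
    samples = [f"s{i}" for i in range(n1 + n2)]
    return DesignTable(treatment=pd.Series(
        ["a"] * n1 + ["b"] * n2, index=samples))


def frame(rows, design):
    return pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))],
                        columns=design.samples)


class TestDEG:
    def test_symmetric_groups_give_p_one(self):
        """A configuration with identical group statistics has t p-value 1."""
        design = design_of(2, 2)
        expr = frame([[1.0, 3.0, 1.0, 3.0]], design)
        res = deg_test(expr, design)
        assert res.t_pvalue.iloc[0] == pytest.approx(1.0)

    def test_clear_separation(self):
        design = design_of(3, 3)
        jitter = np.array([0, 1e-4, -1e-4])
        expr = frame([np.concatenate([1.0 + jitter, 2.0 + jitter])], design)
        res = deg_test(expr, design, pseudocount=0.0)
        assert res.t_pvalue.iloc[0] < 1e-8
        assert res.log2_fold_change.iloc[0] == pytest.approx(1.0, abs=1e-3)

    def test_t_matches_textbook_formula(self):
        """The reported t p-value equals the pooled-variance closed form."""
        rng = np.random.default_rng(0)
        design = design_of(5, 7)
        a, b = rng.normal(0, 1, 5), rng.normal(0.5, 1, 7)
        expr = frame([np.concatenate([a, b])], design)
        res = deg_test(expr, design)
        n1, n2 = 5, 7
        sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
        t = (b.mean() - a.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        p = 2 * stats.t.sf(abs(t), n1 + n2 - 2)
        assert res.t_pvalue.iloc[0] == pytest.approx(p, rel=1e-10)

    def test_bh_fdr_hand_computation(self):
        """BH on p = (.01, .02, .03, .04) gives q = .04 everywhere."""
        rng = np.random.default_rng(1)
        design = design_of(3, 3)
        # four features engineered to produce increasing p-values, then
        # check the BH arithmetic on whatever p-values come out
        expr = frame(rng.normal(0, 1, (4, 6)), design)
        res = deg_test(expr, design)
        p = np.sort(res.t_pvalue.to_numpy())
        m = len(p)
        expected = np.minimum.accumulate((p * m / np.arange(1, m + 1))[::-1])[::-1]
        expected = np.minimum(expected, 1.0)
        got = np.sort(res.fdr.to_numpy())
        assert np.allclose(got, np.sort(expected), atol=1e-12)

    def test_bh_is_monotone(self):
        rng = np.random.default_rng(2)
        design = design_of(4, 4)
        expr = frame(rng.normal(0, 1, (50, 8)), design)
        res = deg_test(expr, design).sort_values("t_pvalue")
        assert (np.diff(res.fdr.to_numpy()) >= -1e-15).all()

    def test_small_group_rejected(self):
        design = DesignTable(treatment=pd.Series(
            ["a", "b", "b", "b"], index=list("wxyz")))
        with pytest.raises(ValueError):
            deg_test(pd.DataFrame([[1, 2, 3, 4]], columns=list("wxyz")),
                     design)


class TestGCDEG:
    def test_slope_test_equals_pooled_t(self):
        """The uncontrolled slope p equals the two-group Student t p."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            n1, n2 = rng.integers(3, 10, size=2)
            design = design_of(int(n1), int(n2))
            y = rng.normal(0, 1, n1 + n2)
            res = gcdeg_test(y, design, None)
            t = stats.ttest_ind(y[n1:], y[:n1], equal_var=True)
            assert abs(res.p_unadjusted - t.pvalue) < 1e-10

    def test_no_snps_reduces_to_uncontrolled(self):
        rng = np.random.default_rng(4)
        design = design_of(5, 5)
        y = rng.normal(0, 1, 10)
        res = gcdeg_test(y, design, np.empty((10, 0)))
        assert res.p_adjusted == pytest.approx(res.p_unadjusted, rel=1e-12)

    def test_complete_confounding_not_significant_after_control(self):
        """A SNP identical to treatment explains the signal away."""
        expr, design, geno, _ = sim_expression(SimConfig(
            seed=5, confounding_rho=1.0, treatment_effect=0.0,
            genotype_effect=2.0, n_genes=1))
        res = gcdeg_test(expr.iloc[0].to_numpy(), design,
                         geno.iloc[0].to_numpy())
        assert res.p_unadjusted < 0.01
        assert res.p_adjusted == 1.0
        assert not res.is_gcdeg

    def test_orthogonal_genotype_keeps_treatment_effect(self):
        expr, design, geno, _ = sim_expression(SimConfig(
            seed=6, confounding_rho=0.0, treatment_effect=3.0,
            genotype_effect=1.0, n_genes=1))
        res = gcdeg_test(expr.iloc[0].to_numpy(), design,
                         geno.iloc[0].to_numpy())
        assert res.is_gcdeg

    def test_effect_recovery_unbiased(self):
        """With orthogonal genotype, the adjusted fit recovers the effect."""
        biases = []
        for seed in range(60):
            expr, design, geno, truth = sim_expression(SimConfig(
                seed=seed, confounding_rho=0.0, treatment_effect=2.0,
                genotype_effect=1.0, n_genes=1, n_samples=20))
            y = expr.iloc[0].to_numpy()
            tr = design.treatment_codes()
            S = geno.iloc[0].to_numpy()[:, None]
            X = np.column_stack([np.ones(20), S, tr])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            biases.append(coef[-1] - 2.0)
        assert abs(np.mean(biases)) < 0.1

    def test_too_many_covariates_rejected(self):
        design = design_of(3, 3)
        with pytest.raises(ValueError, match="covariates"):
            gcdeg_test(np.zeros(6), design, np.eye(6)[:, :4])


class TestVarianceComponents:
    def test_pure_genotype_function(self):
        """Expression that is exactly linear in one SNP: genotype ~ 1."""
        design = design_of(5, 5)
        snp = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, 0], dtype=float)
        y = 3.0 + 2.0 * snp
        treat, geno, resid = variance_components(y, design, snp)
        assert geno == pytest.approx(1.0, abs=1e-9)
        assert treat == pytest.approx(0.0, abs=1e-9)
        assert resid == pytest.approx(0.0, abs=1e-9)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(7)
        design = design_of(6, 6)
        for _ in range(30):
            y = rng.normal(0, 1, 12)
            snp = rng.integers(0, 3, 12).astype(float)
            vc = variance_components(y, design, snp)
            assert sum(vc) == pytest.approx(1.0, abs=1e-9)
            assert all(-1e-12 <= f <= 1 + 1e-12 for f in vc)

    def test_treatment_dominant_when_effect_is_treatment(self):
        expr, design, geno, _ = sim_expression(SimConfig(
            seed=8, confounding_rho=0.0, treatment_effect=5.0,
            genotype_effect=0.0, n_genes=1, n_samples=40))
        treat, geno_f, resid = variance_components(
            expr.iloc[0].to_numpy(), design, geno.iloc[0].to_numpy())
        assert treat > geno_f and treat > resid

    def test_pure_noise_residual_dominates(self):
        expr, design, geno, _ = sim_expression(SimConfig(
            seed=9, confounding_rho=0.0, treatment_effect=0.0,
            genotype_effect=0.0, n_genes=1, n_samples=60))
        treat, geno_f, resid = variance_components(
            expr.iloc[0].to_numpy(), design, geno.iloc[0].to_numpy())
        assert resid > 0.8

    def test_adding_noise_snps_never_raises_residual(self):
        rng = np.random.default_rng(10)
        design = design_of(10, 10)
        y = rng.normal(0, 1, 20)
        snps = rng.integers(0, 3, (20, 4)).astype(float)
        prev = 1.0
        for m in range(5):
            vc = variance_components(y, design, snps[:, :m] if m else None)
            assert vc[2] <= prev + 1e-12
            prev = vc[2]

    def test_zero_variance_warns_all_zero(self):
        design = design_of(3, 3)
        vc = variance_components(np.ones(6), design, None)
        assert vc == (0.0, 0.0, 0.0)


class TestEQTL:
    def loci(self):
        gene_loci = {"gA": ("chr1", 1000, 2000)}
        snp_loci = {"s_cis": ("chr1", 1500), "s_near": ("chr1", 900_000),
                    "s_far": ("chr1", 5_000_000), "s_trans": ("chr2", 1500)}
        return gene_loci, snp_loci

    def test_perfect_additive_fit(self):
        samples = [f"i{k}" for k in range(6)]
        codes = pd.DataFrame([[0, 1, 2, 0, 1, 2]], index=["s_cis"],
                             columns=samples, dtype=float)
        expr = pd.DataFrame([[1.0, 1.5, 2.0, 1.0, 1.5, 2.0]], index=["gA"],
                            columns=samples)
        res = eqtl_scan(expr, codes, {"gA": ("chr1", 1000, 2000)},
                        {"s_cis": ("chr1", 1500)})
        row = res.iloc[0]
        assert row.beta == pytest.approx(0.5, abs=1e-12)
        assert row.pvalue < 1e-10
        assert row.relation == "cis"

    def test_cis_trans_classification(self):
        rng = np.random.default_rng(11)
        samples = [f"i{k}" for k in range(8)]
        gene_loci, snp_loci = self.loci()
        codes = pd.DataFrame(
            rng.integers(0, 3, (4, 8)).astype(float),
            index=list(snp_loci), columns=samples)
        expr = pd.DataFrame(rng.normal(0, 1, (1, 8)), index=["gA"],
                            columns=samples)
        res = eqtl_scan(expr, codes, gene_loci, snp_loci, mode="both")
        rel = dict(zip(res.snp, res.relation))
        assert rel["s_cis"] == "cis"
        assert rel["s_near"] == "cis"       # within the 1 Mb window
        assert rel["s_far"] == "trans"
        assert rel["s_trans"] == "trans"    # different chromosome

    def test_monomorphic_snp_skipped_and_bonferroni_counts_tests(self):
        samples = [f"i{k}" for k in range(6)]
        codes = pd.DataFrame([[1, 1, 1, 1, 1, 1], [0, 1, 2, 0, 1, 2]],
                             index=["mono", "poly"], columns=samples,
                             dtype=float)
        rng = np.random.default_rng(12)
        expr = pd.DataFrame(rng.normal(0, 1, (1, 6)), index=["gA"],
                            columns=samples)
        res = eqtl_scan(expr, codes, {"gA": ("chr1", 0, 100)},
                        {"mono": ("chr1", 10), "poly": ("chr1", 20)})
        assert list(res.snp) == ["poly"]
        assert res.adjusted_pvalue.iloc[0] == pytest.approx(
            min(1.0, res.pvalue.iloc[0] * 1))

    def test_qc_cells_excluded_pairwise(self):
        samples = [f"i{k}" for k in range(6)]
        codes = pd.DataFrame([[0, 1, 2, np.nan, 1, 0]], index=["s1"],
                             columns=samples)
        expr = pd.DataFrame([[0.0, 0.5, 1.0, 99.0, 0.5, 0.0]], index=["gA"],
                            columns=samples)
        res = eqtl_scan(expr, codes, {"gA": ("chr1", 0, 10)},
                        {"s1": ("chr1", 5)})
        assert res.iloc[0].n == 5
        assert res.iloc[0].beta == pytest.approx(0.5, abs=1e-12)


def test_code_genotype_matrix():
    m = pd.DataFrame({"s1": ["hom_ref", "het_mut"],
                      "s2": ["hom_mut", "qc"]})
    coded = code_genotype_matrix(m)
    assert coded.at[0, "s1"] == 0.0
    assert coded.at[0, "s2"] == 2.0
    assert coded.at[1, "s1"] == 1.0
    assert np.isnan(coded.at[1, "s2"])


def test_gcdeg_scan_matrix_interface():
    expr, design, geno, _ = sim_expression(SimConfig(
        seed=13, n_genes=5, confounding_rho=0.0))
    gene_snps = {g: [f"{g}_snp"] for g in expr.index}
    res = gcdeg_scan(expr, design, gene_snps)
    assert len(res) == 5
    assert {"p_unadjusted", "p_adjusted", "is_gcdeg"} <= set(res.columns)
    assert np.allclose(
        res[["vc_treatment", "vc_genotype", "vc_residual"]].sum(axis=1), 1.0)
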