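"""Genotype QC, trait transforms and the linear QTL scan."""
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pqtl.qtl import (
    BlockPartition,
    GeneAnnotation,
    GenotypeMatrix,
    annotate_cis_trans,
    best_per_block,
    compute_maf,
    gwas_linear,
    hwe_exact_test,
    inverse_normal_transform,
    mean_impute,
    prepare_drug_trait,
    qc_filter,
)


def hwe_oracle(n_AA, n_Aa, n_aa):
    """Exact-rational enumeration of the conditional heterozygote distribution."""
    n = n_AA + n_Aa + n_aa
    n_minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    probs = {}
    for h in range(n_minor % 2, n_minor + 1, 2):
        hom_rare = (n_minor - h) // 2
        hom_common = n - h - hom_rare
        probs[h] = Fraction(
            math.factorial(n) * 2**h,
            math.factorial(h) * math.factorial(hom_rare) * math.factorial(hom_common),
        )
    total = sum(probs.values())
    p_obs = probs[n_Aa]
    return float(sum(v for v in probs.values() if v <= p_obs) / total)


class TestMafAndImputation:
    def test_maf_examples(self):
        assert compute_maf([0, 0, 1, 2]) == pytest.approx(0.375)
        assert compute_maf([0, 0, 0]) == 0.0
        assert compute_maf([2, np.nan, 0]) == pytest.approx(0.5)

    def test_maf_all_missing_errors(self):
        with pytest.raises(ValueError):
            compute_maf([np.nan, np.nan])

    def test_mean_impute(self):
        assert mean_impute([0, 2, np.nan]).tolist() == [0, 2, 1]
        x = np.array([0.0, 1.0, 2.0])
        assert mean_impute(x).tolist() == x.tolist()

    def test_imputed_mean_equals_observed_mean(self, rng):
        x = rng.integers(0, 3, size=50).astype(float)
        x[rng.choice(50, 10, replace=False)] = np.nan
        filled = mean_impute(x)
        assert np.nanmean(x) == pytest.approx(filled.mean())
        assert np.var(filled) <= np.nanvar(x) + 1e-12


class TestHWE:
    def test_monomorphic_p_one(self):
        assert hwe_exact_test(0, 0, 25) == 1.0
        assert hwe_exact_test(25, 0, 0) == 1.0

    def test_two_minor_alleles(self):
        # allele count 2: heterozygote configurations h in {0, 2} with
        # conditional probabilities 1/3 and 2/3; observing h=0 gives p=1/3
        assert hwe_exact_test(1, 0, 1) == pytest.approx(1 / 3)
        assert hwe_exact_test(0, 2, 0) == pytest.approx(1.0)

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 0, 5)

    @given(
        st.integers(min_value=0, max_value=20),
        st.integers(min_value=0, max_value=20),
        st.integers(min_value=0, max_value=20),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_enumeration_oracle(self, a, b, c):
        if a + b + c == 0:
            return
        assert hwe_exact_test(a, b, c) == pytest.approx(hwe_oracle(a, b, c), abs=1e-12)


class TestQCFilter:
    @staticmethod
    def _make_geno(dosages):
        dosages = np.asarray(dosages, dtype=float)
        m = len(dosages)
        variants = pd.DataFrame(
            {"chrom": "1", "pos": np.arange(1, m + 1) * 100},
            index=pd.Index([f"v{i}" for i in range(m)], name="variant_id"),
        )
        cols = [f"i{j}" for j in range(dosages.shape[1])]
        return GenotypeMatrix(variants, pd.DataFrame(dosages, index=variants.index, columns=cols))

    def test_constructed_violations(self, rng):
        n = 60
        good = [rng.binomial(2, 0.3, n) for _ in range(7)]
        rare = [rng.binomial(2, 0.01, n) for _ in range(2)]  # MAF < 0.05
        # strong HWE violation: all heterozygotes
        hwe_bad = [np.ones(n)]
        geno = self._make_geno(np.array(good + rare + hwe_bad))
        kept = qc_filter(geno)
        assert kept.n_variants == 7
        assert set(kept.variants.index) == {f"v{i}" for i in range(7)}

    def test_idempotent(self, cohort):
        once = qc_filter(cohort["geno"])
        twice = qc_filter(once)
        assert list(once.variants.index) == list(twice.variants.index)


class TestTransforms:
    def test_int_middle_of_three_is_zero(self):
        out = inverse_normal_transform([5.0, 1.0, 3.0])
        assert out[np.argsort([5.0, 1.0, 3.0])[1]] == pytest.approx(0.0)

    def test_int_monotone_and_symmetric(self, rng):
        x = rng.normal(size=41)
        out = inverse_normal_transform(x)
        assert np.all(np.diff(out[np.argsort(x)]) >= 0)
        assert out.mean() == pytest.approx(0.0, abs=1e-10)

    def test_int_ties_share_midrank_value(self):
        x = np.array([1.0, 2.0, 2.0, 3.0])
        out = inverse_normal_transform(x)
        # midrank of the tied pair is 2.5 -> Phi^-1((2.5 - 0.5)/4)
        expected = stats.norm.ppf(2.0 / 4.0)
        assert out[1] == out[2] == pytest.approx(expected)

    def test_int_constant_errors(self):
        with pytest.raises(ValueError):
            inverse_normal_transform([1.0, 1.0, 1.0])

    def test_int_output_near_normal(self):
        # rank-based quantiles should sail through a normality test
        ok = 0
        for seed in range(20):
            x = np.random.default_rng(seed).exponential(size=68)
            out = inverse_normal_transform(x)
            ok += stats.shapiro(out).pvalue > 0.05
        assert ok >= 20 * 0.99 - 1

    def test_prepare_drug_trait_log(self):
        out, sw_p = prepare_drug_trait([1.0, math.e, math.e**2])
        assert out == pytest.approx([0.0, 1.0, 2.0])

    def test_prepare_drug_trait_nonpositive_errors(self):
        with pytest.raises(ValueError, match="indices"):
            prepare_drug_trait([1.0, -2.0, 3.0])

    def test_prepare_drug_trait_lognormal_passes_gate(self):
        ok = 0
        for seed in range(40):
            x = np.exp(np.random.default_rng(seed).normal(size=68))
            _, sw_p = prepare_drug_trait(x)
            ok += sw_p > 0.001
        assert ok >= 38  # >= 95% of seeds

    def test_prepare_drug_trait_warns_but_returns_on_heavy_tails(self):
        # strongly bimodal on the log scale: fails the gate but still returns
        x = np.concatenate([np.full(50, 1e-6), np.full(50, 1e6)])
        x *= 1 + 0.01 * np.random.default_rng(0).random(100)
        with pytest.warns(UserWarning):
            out, sw_p = prepare_drug_trait(x)
        assert out.shape == x.shape and sw_p <= 0.001


def _random_geno(rng, m, n):
    variants = pd.DataFrame(
        {"chrom": "1", "pos": np.arange(1, m + 1) * 10},
        index=pd.Index([f"v{i}" for i in range(m)], name="variant_id"),
    )
    dos = rng.binomial(2, 0.3, size=(m, n)).astype(float)
    return GenotypeMatrix(variants, pd.DataFrame(dos, index=variants.index,
                                                 columns=[f"i{j}" for j in range(n)]))


class TestGwasLinear:
    def test_matches_correlation_test_oracle(self):
        # p from the regression t-test must equal the closed-form
        # correlation test t = r sqrt((n-2)/(1-r^2)) on random data
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(12, 40))
            geno = _random_geno(rng, 5, n)
            trait = pd.Series(rng.normal(size=n), index=geno.individuals)
            res = gwas_linear(geno, trait)
            for vid in geno.variants.index:
                x = geno.dosages.loc[vid].to_numpy()
                if x.var() == 0:
                    assert np.isnan(res.loc[vid, "p"])
                    continue
                r = np.corrcoef(x, trait.to_numpy())[0, 1]
                t = r * np.sqrt((n - 2) / (1 - r**2))
                p_oracle = 2 * stats.t.sf(abs(t), n - 2)
                assert res.loc[vid, "p"] == pytest.approx(p_oracle, abs=1e-10)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(5)
        geno = _random_geno(rng, 5000, 100)
        trait = pd.Series(rng.normal(size=100), index=geno.individuals)
        res = gwas_linear(geno, trait)
        ps = res["p"].dropna()
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_planted_variant_attains_min_p(self):
        rng = np.random.default_rng(6)
        geno = _random_geno(rng, 50, 500)
        trait = pd.Series(rng.normal(size=500), index=geno.individuals)
        trait = trait + 0.8 * geno.dosages.loc["v7"].to_numpy()
        res = gwas_linear(geno, trait)
        assert res["p"].idxmin() == "v7"

    def test_zero_variance_variant_emits_nan_row(self):
        rng = np.random.default_rng(7)
        geno = _random_geno(rng, 3, 30)
        geno.dosages.loc["v1"] = 1.0
        trait = pd.Series(rng.normal(size=30), index=geno.individuals)
        res = gwas_linear(geno, trait)
        assert res.loc["v1", ["beta", "se", "p"]].astype(float).isna().all()
        assert len(res) == 3


class TestBestPerBlock:
    @staticmethod
    def _setup(ps, positions=None):
        m = len(ps)
        positions = positions or list(range(100, 100 + m))
        variants = pd.DataFrame(
            {"chrom": "1", "pos": positions},
            index=pd.Index([f"v{i}" for i in range(m)], name="variant_id"),
        )
        geno = GenotypeMatrix(
            variants, pd.DataFrame(np.ones((m, 2)), index=variants.index, columns=["a", "b"])
        )
        blocks = BlockPartition(
            pd.DataFrame({"chrom": ["1"], "start": [0], "end": [10_000]},
                         index=pd.Index(["b0"], name="block_id"))
        )
        qtl = pd.DataFrame(
            {"variant_id": variants.index, "trait_id": "t", "trait_class": "drug",
             "beta": 1.0, "se": 1.0, "p": ps, "n": 2}
        )
        return qtl, geno, blocks

    def test_min_p_kept(self):
        qtl, geno, blocks = self._setup([0.5, 0.01, 0.2])
        out = best_per_block(qtl, geno, blocks)
        assert list(out["variant_id"]) == ["v1"]

    def test_tie_breaks_to_lowest_position(self):
        qtl, geno, blocks = self._setup([0.01, 0.01, 0.5])
        out = best_per_block(qtl, geno, blocks)
        assert list(out["variant_id"]) == ["v0"]

    def test_singleton_blocks_identity(self, cohort):
        cfg, geno, blocks = cohort["cfg"], cohort["geno"], cohort["blocks"]
        trait = cohort["phen"]["growth"]
        qtl = gwas_linear(geno, trait, trait_id="growth", trait_class="drug")
        pruned = best_per_block(qtl, geno, blocks)
        assert len(pruned) == blocks.n_blocks

    def test_unmapped_variant_errors(self):
        qtl, geno, blocks = self._setup([0.5, 0.1, 0.2], positions=[100, 200, 99_999_999])
        with pytest.raises(ValueError, match="not mapped"):
            best_per_block(qtl, geno, blocks)


class TestCisTrans:
    @staticmethod
    def _annot(pos, gene_chrom="1", tss=2_000_000, tes=2_020_000):
        variants = pd.DataFrame({"chrom": ["1"], "pos": [pos]},
                                index=pd.Index(["v0"], name="variant_id"))
        geno = GenotypeMatrix(
            variants, pd.DataFrame([[0.0, 1.0]], index=variants.index, columns=["a", "b"])
        )
        genes = GeneAnnotation(
            pd.DataFrame({"chrom": [gene_chrom], "tss": [tss], "tes": [tes], "strand": ["+"]},
                         index=pd.Index(["G"], name="gene_id"))
        )
        qtl = pd.DataFrame({"variant_id": ["v0"], "trait_id": ["P"], "trait_class": ["protein"],
                            "beta": [1.0], "se": [1.0], "p": [1e-6], "n": [2]})
        return annotate_cis_trans(qtl, geno, genes, {"P": "G"})

    def test_inside_window_is_cis(self):
        assert self._annot(2_000_000 - 999_999)["cis_trans"].iloc[0] == "cis"

    def test_outside_window_is_trans(self):
        assert self._annot(2_020_000 + 1_000_001)["cis_trans"].iloc[0] == "trans"

    def test_other_chromosome_is_trans(self):
        assert self._annot(2_000_000, gene_chrom="2")["cis_trans"].iloc[0] == "trans"

    def test_missing_gene_mapping_warns_unknown(self):
        variants = pd.DataFrame({"chrom": ["1"], "pos": [100]},
                                index=pd.Index(["v0"], name="variant_id"))
        geno = GenotypeMatrix(
            variants, pd.DataFrame([[0.0, 1.0]], index=variants.index, columns=["a", "b"])
        )
        genes = GeneAnnotation(pd.DataFrame({"chrom": ["1"], "tss": [1], "tes": [2]},
                                            index=pd.Index(["G"], name="gene_id")))
        qtl = pd.DataFrame({"variant_id": ["v0"], "trait_id": ["P"], "trait_class": ["protein"],
                            "beta": [1.0], "se": [1.0], "p": [1e-6], "n": [2]})
        with pytest.warns(UserWarning):
            out = annotate_cis_trans(qtl, geno, genes, {})
        assert out["cis_trans"].iloc[0] == "unknown"
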