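"""Mixed-effect protein-drug association, q-values, variance components, siRNA."""
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pqtl.assoc import (
    fit_fixed_association,
    fit_mem_association,
    growth_adjusted_association,
    growth_correlation,
    sirna_effect,
    storey_qvalues,
    variance_components,
)
from pqtl.simulate import simulate_sirna_experiment


def long_frame(values, individuals=None):
    """(n_ind, n_thaw) array -> tidy (individual, thaw, value)."""
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    individuals = individuals or [f"I{i}" for i in range(n)]
    return pd.DataFrame(
        {
            "individual": np.repeat(individuals, k),
            "thaw": np.tile(np.arange(1, k + 1), n),
            "value": values.ravel(),
        }
    )


class TestMemAssociation:
    def test_identical_thaws_equals_ols_on_means(self, rng):
        n = 20
        base = rng.normal(size=n)
        df = long_frame(np.repeat(base[:, None], 3, axis=1))
        pheno = pd.Series(rng.normal(size=n), index=[f"I{i}" for i in range(n)])
        mem = fit_mem_association(df, pheno, standardize=False)
        means = pd.DataFrame({"value": base, "pheno": pheno.to_numpy()})
        ols = stats.linregress(means["pheno"], means["value"])
        assert mem.model == "MEM"
        assert mem.beta == pytest.approx(ols.slope, abs=1e-6)

    def test_zero_variance_phenotype_errors(self, rng):
        df = long_frame(rng.normal(size=(12, 3)))
        pheno = pd.Series(1.0, index=[f"I{i}" for i in range(12)])
        with pytest.raises(ValueError, match="degenerate covariate"):
            fit_mem_association(df, pheno)

    def test_singleton_groups_fall_back_to_ols(self, rng):
        df = long_frame(rng.normal(size=(15, 1)))
        pheno = pd.Series(rng.normal(size=15), index=[f"I{i}" for i in range(15)])
        with pytest.warns(UserWarning, match="single replicate"):
            res = fit_mem_association(df, pheno)
        fixed = fit_fixed_association(df, pheno)
        assert res.beta == pytest.approx(fixed.beta)
        assert res.p == pytest.approx(fixed.p)

    def test_conflicting_thaw_attenuates_vs_fixed(self):
        # two thaws track the phenotype, the third reverses it: averaging
        # hides the inconsistency, the replicate-aware model does not
        rng = np.random.default_rng(3)
        n = 30
        pheno = rng.normal(size=n)
        consistent = 0.6 * pheno[:, None] + 0.3 * rng.normal(size=(n, 2))
        outlier = -1.0 * pheno[:, None] + 0.3 * rng.normal(size=(n, 1))
        df = long_frame(np.hstack([consistent, outlier]))
        ph = pd.Series(pheno, index=[f"I{i}" for i in range(n)])
        fixed = fit_fixed_association(df, ph)
        mem = fit_mem_association(df, ph)
        assert fixed.p < 0.05
        assert mem.p > fixed.p

    def test_fixed_beta_sign_matches_covariance_of_means(self, rng):
        vals = rng.normal(size=(15, 3))
        pheno = pd.Series(rng.normal(size=15), index=[f"I{i}" for i in range(15)])
        res = fit_fixed_association(long_frame(vals), pheno)
        cov = np.cov(vals.mean(axis=1), pheno.to_numpy())[0, 1]
        assert np.sign(res.beta) == np.sign(cov)

    def test_planted_effect_recovered_with_replicates(self):
        # protein = 0.5 * phenotype + individual + thaw noise
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n, k = 68, 3
            pheno = rng.normal(size=n)
            vals = (
                0.5 * pheno[:, None]
                + rng.normal(0, np.sqrt(0.95), size=(n, 1))
                + rng.normal(0, np.sqrt(0.05), size=(n, k))
            )
            df = long_frame(vals)
            ph = pd.Series(pheno, index=[f"I{i}" for i in range(n)])
            res = fit_mem_association(df, ph, standardize=False)
            hits += abs(res.beta - 0.5) <= 2 * res.se
        assert hits >= 18  # ~2 SE coverage


class TestStoreyQvalues:
    def test_single_p_of_one(self):
        assert storey_qvalues([1.0]).tolist() == [1.0]

    def test_bh_equivalence_when_pi0_is_one(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=50)  # m < 100 -> pi0 = 1 -> exactly BH
        q = storey_qvalues(p)
        _, bh, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, bh)

    def test_uniform_p_pi0_near_one(self, rng):
        p = rng.uniform(size=1000)
        q = storey_qvalues(p)
        # with pi0 in [0.8, 1] capped at 1, max q equals pi0
        assert 0.8 <= q.max() <= 1.0

    def test_q_monotone_in_p(self, rng):
        p = rng.uniform(size=300)
        q = storey_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_invalid_p_errors(self):
        with pytest.raises(ValueError):
            storey_qvalues([0.5, 0.0])
        with pytest.raises(ValueError):
            storey_qvalues([0.5, 1.5])

    def test_fdr_control_with_planted_nonnulls(self):
        # 10% non-null tests; thresholding q <= 0.1 keeps FDR near 0.1
        fdrs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            m, m1 = 1000, 100
            z = rng.normal(size=m)
            z[:m1] += 3.5
            p = stats.norm.sf(z)
            p = np.clip(p, np.nextafter(0, 1), 1.0)
            q = storey_qvalues(p)
            sel = q <= 0.1
            if sel.sum():
                fdrs.append((sel & (np.arange(m) >= m1)).sum() / sel.sum())
        assert np.mean(fdrs) <= 0.1 + 0.03


class TestGrowth:
    def test_monotone_pairs(self):
        x = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=list("abcde"))
        up = pd.Series([2.0, 3.0, 5.0, 7.0, 11.0], index=list("abcde"))
        rho, _ = growth_correlation(x, up)
        assert rho == pytest.approx(1.0)
        rho, _ = growth_correlation(x, -up)
        assert rho == pytest.approx(-1.0)

    def test_ties_match_midrank_oracle(self):
        x = pd.Series([1.0, 2.0, 2.0, 3.0, 4.0, 4.0], index=list("abcdef"))
        y = pd.Series([5.0, 5.0, 6.0, 7.0, 8.0, 9.0], index=list("abcdef"))
        rho, _ = growth_correlation(x, y)
        rx = stats.rankdata(x)  # midranks
        ry = stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle)

    def test_constant_errors(self):
        x = pd.Series([1.0] * 6, index=list("abcdef"))
        y = pd.Series(np.arange(6.0), index=list("abcdef"))
        with pytest.raises(ValueError):
            growth_correlation(x, y)

    def test_orthogonal_growth_leaves_beta(self, rng):
        n = 40
        ind = [f"I{i}" for i in range(n)]
        pheno = pd.Series(rng.normal(size=n), index=ind)
        growth = pd.Series(rng.normal(size=n), index=ind)
        vals = 0.5 * pheno.to_numpy()[:, None] + rng.normal(0, 0.5, size=(n, 3))
        df = long_frame(vals, ind)
        unadj, adj = growth_adjusted_association(df, pheno, growth, standardize=False)
        assert adj is not None
        assert abs(adj.beta - unadj.beta) <= 2 * unadj.se

    def test_mediated_effect_vanishes_after_adjustment(self):
        # protein driven by growth; phenotype driven by growth: the
        # protein-phenotype association is pure mediation
        rng = np.random.default_rng(8)
        n = 60
        ind = [f"I{i}" for i in range(n)]
        growth = pd.Series(rng.normal(size=n), index=ind)
        pheno = pd.Series(0.9 * growth.to_numpy() + 0.3 * rng.normal(size=n), index=ind)
        vals = 0.9 * growth.to_numpy()[:, None] + 0.3 * rng.normal(size=(n, 3))
        df = long_frame(vals, ind)
        unadj, adj = growth_adjusted_association(df, pheno, growth, standardize=False)
        assert unadj.p < 0.05
        assert adj.p > 0.05

    def test_zero_variance_growth_errors(self, rng):
        n = 20
        ind = [f"I{i}" for i in range(n)]
        pheno = pd.Series(rng.normal(size=n), index=ind)
        growth = pd.Series(1.0, index=ind)
        df = long_frame(rng.normal(size=(n, 3)), ind)
        with pytest.raises(ValueError, match="growth"):
            growth_adjusted_association(df, pheno, growth)


class TestVarianceComponents:
    def test_fractions_sum_to_one(self, rng):
        df = long_frame(rng.normal(size=(20, 3)))
        vd = variance_components(df)
        total = (vd.fraction_individual + vd.fraction_thaw_within_individual
                 + vd.fraction_culture_within_thaw + vd.fraction_residual)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_pure_noise_small_grouping_fractions(self):
        # pilot-style data with enough sub-thaw replication that grouping
        # components are well resolved: iid noise yields near-zero
        # individual/thaw/culture fractions
        rng = np.random.default_rng(1)
        rows = []
        for i in range(50):
            for t in range(3):
                for c in range(20):
                    rows.append({"individual": f"I{i}", "thaw": t, "culture": c,
                                 "value": rng.normal()})
        vd = variance_components(pd.DataFrame(rows))
        assert vd.fraction_individual < 0.02
        assert vd.fraction_thaw_within_individual < 0.02
        assert vd.fraction_culture_within_thaw < 0.02

    def test_zero_culture_variance_recovered_as_zero(self):
        rng = np.random.default_rng(2)
        rows = []
        for i in range(20):
            b = rng.normal(0, 1.0)
            for t in range(3):
                u = rng.normal(0, 0.5)
                for c in range(3):
                    rows.append({"individual": f"I{i}", "thaw": t, "culture": c,
                                 "value": b + u + rng.normal(0, 0.3)})
        vd = variance_components(pd.DataFrame(rows))
        assert vd.fraction_culture_within_thaw < 1e-4
        assert vd.fraction_individual > 0.5

    def test_single_individual_errors(self, rng):
        df = long_frame(rng.normal(size=(1, 3)))
        with pytest.raises(ValueError):
            variance_components(df)

    def test_thaw_fraction_recovery_median(self):
        # one measurement per (individual, thaw): within-individual variance
        # is attributed to the thaw component, the design's replicate unit
        from pqtl.simulate import SimulationConfig, simulate_genotypes, simulate_protein_matrix

        cfg = SimulationConfig(n_individuals=68, n_variants=10, n_blocks=2,
                               n_antibodies=40, seed=3)
        geno, _ = simulate_genotypes(cfg)
        prot, truth = simulate_protein_matrix(cfg, geno)
        fracs = [
            variance_components(grp, ab).fraction_thaw_within_individual
            for ab, grp in prot.long().groupby("antibody")
        ]
        assert abs(np.median(fracs) - 0.0529) < 0.02


class TestSirna:
    def test_identical_responses_null(self):
        rows = []
        for li in range(3):
            for xi in range(2):
                for kd in (0, 1):
                    for _ in range(4):
                        rows.append({"line": li, "experiment": xi, "knockdown": kd,
                                     "response": 100.0 + 10 * li + 5 * xi})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sirna_effect(pd.DataFrame(rows))
        assert abs(res.beta_log) < 1e-8
        assert res.p > 0.9

    def test_null_effect_within_two_se(self):
        tab = simulate_sirna_experiment(0.0, 3, 2, seed=1)
        res = sirna_effect(tab)
        assert res.p > 0.01  # no planted effect

    def test_planted_increase_recovered(self):
        tab = simulate_sirna_experiment(0.19, 3, 2, seed=2)
        res = sirna_effect(tab)
        assert res.beta_log > 0
        assert res.p < 0.05

    def test_single_line_warns_and_fits(self):
        tab = simulate_sirna_experiment(-0.119, 1, 2, seed=3)
        with pytest.warns(UserWarning, match="single cell line"):
            res = sirna_effect(tab)
        assert res.pct_change < 0

    def test_single_line_single_experiment_ols(self):
        tab = simulate_sirna_experiment(-0.119, 1, 1, seed=4)
        with pytest.warns(UserWarning):
            res = sirna_effect(tab)
        assert res.model == "fixed"

    def test_one_condition_errors(self):
        tab = simulate_sirna_experiment(0.0, 2, 2, seed=5)
        with pytest.raises(ValueError):
            sirna_effect(tab[tab["knockdown"] == 1])
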