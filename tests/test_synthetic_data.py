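"""Tests of the mini-exome synthetic data generator."""
import numpy as np
import pytest
from scipy.stats import pearsonr

import raregene as rg
from raregene.errors import ParameterError, StateError
from raregene.synthetic_data import DEFAULT_ARCHITECTURES


class TestSimulateGenotypes:
    def test_rare_fraction_matches_mini_exome_target(self):
        # the emulated exome has 21,355/24,487 = 87.2% SNPs with MAF < 5%
        geno = rg.simulate_genotypes(697, 5000, seed=7)
        rare = (geno.maf < 0.05).mean()
        assert 0.82 <= rare <= 0.92

    def test_counts_and_maf_bounds_at_point_mass_half(self):
        geno = rg.simulate_genotypes(10, 1, maf_dist={"kind": "point", "value": 0.5}, seed=3)
        assert set(np.unique(geno.counts)) <= {0, 1, 2}
        assert 0.0 <= geno.maf[0] <= 0.5
        geno.validate()

    def test_same_seed_is_bit_identical(self):
        a = rg.simulate_genotypes(50, 200, seed=11)
        b = rg.simulate_genotypes(50, 200, seed=11)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.maf, b.maf)
        assert list(a.gene_of) == list(b.gene_of)

    def test_container_invariants_hold(self):
        geno = rg.simulate_genotypes(100, 2000, seed=5)
        geno.validate()  # counts in {0,1,2}, maf consistent, unique ids
        assert all(len(geno.gene_columns(g)) >= 1 for g in geno.genes)

    def test_hardy_weinberg_heterozygosity(self):
        # at fixed q=0.1, mean heterozygote fraction ~ 2q(1-q) = 0.18
        n, m, q = 400, 2000, 0.1
        geno = rg.simulate_genotypes(n, m, maf_dist={"kind": "point", "value": q}, seed=13)
        het = (geno.counts == 1).mean()
        se = np.sqrt(2 * q * (1 - q) * (1 - 2 * q * (1 - q)) / (n * m))
        assert abs(het - 2 * q * (1 - q)) < 3 * se

    def test_monomorphic_snps_are_kept_and_flagged(self):
        geno = rg.simulate_genotypes(30, 500, maf_dist={"kind": "point", "value": 0.005},
                                     seed=2)
        mono = geno.is_monomorphic
        assert mono.any()                      # tiny q at n=30 yields empty columns
        assert geno.counts[:, mono].sum() == 0

    def test_invalid_parameters_raise(self):
        with pytest.raises(ParameterError):
            rg.simulate_genotypes(1, 10, seed=0)
        with pytest.raises(ParameterError):
            rg.simulate_genotypes(10, 10, maf_dist={"kind": "point", "value": 0.7}, seed=0)


class TestSimulateCovariates:
    def test_expected_shape_and_levels(self):
        cov = rg.simulate_covariates(697, 7, seed=1)
        assert cov.n_individuals == 697
        assert cov.table["population"].nunique() == 7
        X = cov.design_matrix()
        assert X.shape == (697, 1 + 3 + 6)  # intercept, age/sex/smoke, 6 pop dummies

    def test_single_population_drops_all_indicators(self):
        cov = rg.simulate_covariates(20, 1, seed=1)
        assert cov.design_matrix(add_intercept=False).shape[1] == 3

    def test_determinism(self):
        a = rg.simulate_covariates(50, 3, seed=9)
        b = rg.simulate_covariates(50, 3, seed=9)
        assert a.table.equals(b.table)


class TestAssignEffects:
    def test_maf_linked_effects_decrease_with_frequency(self):
        geno = rg.simulate_genotypes(400, 800, seed=21)
        truth = rg.assign_effects(geno, "q2", 5, "maf_linked", seed=22)
        eff = truth.effects["q2"]
        q = np.array([geno.maf[geno.snp_index(s)] for s in eff.index])
        order = np.argsort(q)
        # |beta| = c|log10 q| is strictly decreasing in q (up to ties in q)
        b = np.abs(eff.to_numpy())[order]
        qq = q[order]
        for i in range(len(b) - 1):
            if qq[i + 1] > qq[i]:
                assert b[i + 1] < b[i]

    def test_maf_independent_is_uncorrelated_over_seeds(self):
        geno = rg.simulate_genotypes(500, 2000, seed=31)
        pvals = []
        for seed in range(25):
            truth = rg.assign_effects(geno, "q1", 25, "maf_independent", seed=seed)
            eff = truth.effects["q1"]
            q = np.array([geno.maf[geno.snp_index(s)] for s in eff.index])
            pvals.append(pearsonr(q, np.abs(eff.to_numpy()))[1])
        # under independence p-values are uniform: most should exceed 0.05
        assert np.mean(np.array(pvals) > 0.05) >= 0.6

    def test_zero_causal_genes_gives_empty_truth(self):
        geno = rg.simulate_genotypes(50, 100, seed=41)
        truth = rg.assign_effects(geno, "q4", 0, seed=4)
        assert len(truth.effects["q4"]) == 0

    def test_causal_snps_are_rare_nonsynonymous(self):
        geno = rg.simulate_genotypes(300, 1000, seed=51)
        truth = rg.assign_effects(geno, "q1", 10, "maf_independent", seed=52)
        for s in truth.causal_snps("q1"):
            j = geno.snp_index(s)
            assert geno.annotation[j] == "nonsynonymous"
            assert 0 < geno.maf[j] < 0.05

    def test_unknown_trait_rejected(self):
        geno = rg.simulate_genotypes(50, 100, seed=61)
        with pytest.raises(ParameterError):
            rg.assign_effects(geno, "q9", 1, seed=0)


class TestSimulatePhenotypes:
    def test_variance_decomposition_of_generating_model(self):
        # Q1-like architecture (0.206, 0.161, 0.633) recovered empirically
        geno = rg.simulate_genotypes(697, 2000, seed=71)
        cov = rg.simulate_covariates(697, 7, seed=72)
        truth = rg.assign_effects(geno, "q1", 9, "maf_independent", seed=73)
        pheno = rg.simulate_phenotypes(geno, cov, truth, R=200, seed=74)
        Y = pheno.trait_matrix("q1")
        eff = truth.effects["q1"]
        idx = [geno.snp_index(s) for s in eff.index]
        genetic = geno.counts[:, idx].astype(float) @ eff.to_numpy()
        env = (Y - genetic[:, None]).mean(axis=1)  # residuals average out over R=200
        resid_var = (Y - genetic[:, None] - env[:, None]).var()
        target = DEFAULT_ARCHITECTURES["q1"]
        assert abs(genetic.var() - target[0]) < 0.03
        assert abs(env.var() - target[1]) < 0.03
        assert abs(resid_var - target[2]) < 0.03

    def test_pure_noise_limit(self):
        geno = rg.simulate_genotypes(500, 100, seed=81)
        cov = rg.simulate_covariates(500, 3, seed=82)
        truth = rg.assign_effects(geno, "q4", 0, architecture=(0.0, 0.0, 1.0), seed=83)
        pheno = rg.simulate_phenotypes(geno, cov, truth, R=20, seed=84)
        v = pheno.trait_matrix("q4").var()
        assert abs(v - 1.0) < 0.05

    def test_genetic_component_fixed_across_replicates(self):
        geno = rg.simulate_genotypes(300, 500, seed=91)
        cov = rg.simulate_covariates(300, 3, seed=92)
        truth = rg.assign_effects(geno, "q1", 5, seed=93)
        pheno = rg.simulate_phenotypes(geno, cov, truth, R=2, seed=94)
        Y = pheno.trait_matrix("q1")
        diff = Y[:, 0] - Y[:, 1]
        # the fixed part (genetic + environmental) cancels: only noise remains
        target = DEFAULT_ARCHITECTURES["q1"][2]
        assert abs(diff.var() - 2 * target) < 0.15
        eff = truth.effects["q1"]
        idx = [geno.snp_index(s) for s in eff.index]
        genetic = geno.counts[:, idx].astype(float) @ eff.to_numpy()
        assert abs(pearsonr(diff, genetic)[0]) < 0.15

    def test_binary_prevalence_near_target(self):
        geno = rg.simulate_genotypes(697, 500, seed=95)
        cov = rg.simulate_covariates(697, 3, seed=96)
        truth = rg.assign_effects(geno, "affected", 5, seed=97)
        pheno = rg.simulate_phenotypes(geno, cov, truth, R=10, prevalence=0.3, seed=98)
        prev = pheno.trait_matrix("affected").mean()
        assert abs(prev - 0.3) < 0.05

    def test_unattainable_fractions_rejected(self):
        geno = rg.simulate_genotypes(50, 100, seed=99)
        with pytest.raises(ParameterError):
            rg.assign_effects(geno, "q1", 2, architecture=(0.7, 0.5, 0.2), seed=1)


class TestInjectTwins:
    def test_injected_twins_are_exact_copies(self):
        geno = rg.simulate_genotypes(100, 300, seed=101)
        truth = rg.assign_effects(geno, "q1", 4, seed=102)
        twinned, new_truth = rg.inject_twins(geno, truth, 5, seed=103)
        assert len(new_truth.twin_map) == 5
        for twin, src in new_truth.twin_map.items():
            jt, js = twinned.snp_index(twin), twinned.snp_index(src)
            assert np.array_equal(twinned.counts[:, jt], twinned.counts[:, js])
        twinned.validate()

    def test_zero_twins_is_identity(self):
        geno = rg.simulate_genotypes(50, 100, seed=111)
        truth = rg.assign_effects(geno, "q1", 2, seed=112)
        out, t2 = rg.inject_twins(geno, truth, 0, seed=113)
        assert np.array_equal(out.counts, geno.counts)
        assert t2.twin_map == {}

    def test_twins_prefer_noncausal_genes(self):
        geno = rg.simulate_genotypes(100, 500, seed=121)
        truth = rg.assign_effects(geno, "q1", 3, seed=122)
        twinned, t2 = rg.inject_twins(geno, truth, 8, seed=123)
        causal_genes = truth.causal_genes(geno, "q1")
        for twin in t2.twin_map:
            assert twinned.gene_of[twinned.snp_index(twin)] not in causal_genes

    def test_no_causal_snps_is_state_error(self):
        geno = rg.simulate_genotypes(50, 100, seed=131)
        truth = rg.assign_effects(geno, "q4", 0, seed=132)
        with pytest.raises(StateError):
            rg.inject_twins(geno, truth, 1, seed=133)
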