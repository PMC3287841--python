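"""Tests of gene scores and the covariate-adjusted burden association test."""
import numpy as np
import pytest

import raregene as rg
from conftest import make_genotype_matrix
from raregene.collapsing_tests import (
    burden_null_cache, build_score, cmc_group_scores, collapse_indicator,
    collapse_proportion, fit_burden_association, madsen_browning_weights,
    weighted_sum_score,
)
from raregene.errors import ParameterError, UndefinedScoreError
from raregene.types import GeneScore


class TestIndicatorScore:
    def test_definition_on_hand_cases(self, tiny_geno):
        s = collapse_indicator(tiny_geno, "A")
        # individuals 1,2,4 carry a rare minor allele in gene A
        assert list(s.values[:5]) == [1.0, 1.0, 0.0, 1.0, 0.0]
        assert np.all(s.values[5:] == 0)

    def test_common_snp_excluded(self, tiny_geno):
        # individual 3 (row index 2) carries B1 (MAF 0.3, common) and B2 (rare)
        s = collapse_indicator(tiny_geno, "B")
        assert s.values[2] == 1.0      # via rare B2
        assert s.values[3] == 0.0      # carries only the common B1
        assert s.n_snps_used == 2      # B2, B3 are rare; B1 excluded

    def test_no_rare_snps_warns_and_zeroes(self, caplog):
        geno = make_genotype_matrix(
            np.array([[1, 2], [1, 0], [2, 1], [0, 1]]), ["G", "G"])
        with caplog.at_level("WARNING"):
            s = collapse_indicator(geno, "G", maf_threshold=0.05)
        assert np.all(s.values == 0)
        assert any("no SNPs" in m for m in caplog.messages)


class TestProportionScore:
    def test_fraction_of_rare_carriers(self, tiny_geno):
        s = collapse_proportion(tiny_geno, "A")
        assert s.values[1] == pytest.approx(1 / 3)   # carries A1 only
        assert s.values[0] == pytest.approx(1 / 3)   # carries A3 only

    def test_carrier_at_all_rare_snps_scores_one(self):
        geno = make_genotype_matrix(np.array([[1, 1], [0, 0], [0, 0], [0, 0],
                                              [0, 0], [0, 0], [0, 0], [0, 0],
                                              [0, 0], [0, 0], [0, 0], [0, 0]]),
                                    ["G", "G"])
        assert collapse_proportion(geno, "G").values[0] == 1.0

    def test_homozygous_minor_counts_as_presence(self):
        # presence (>=1 allele), not dosage: a single count-2 SNP scores 1.0
        geno = make_genotype_matrix(
            np.array([[2], [0], [0], [0], [0], [0], [0], [0], [0], [0],
                      [0], [0], [0], [0], [0], [0], [0], [0], [0], [0],
                      [0], [0], [0], [0], [0]]), ["G"])
        s = collapse_proportion(geno, "G")
        assert s.values[0] == 1.0
        assert collapse_proportion(geno, "G", dosage=True).values[0] == 1.0

    def test_zero_rare_snps_is_undefined(self):
        geno = make_genotype_matrix(np.array([[1], [2], [0], [1]]), ["G"])
        with pytest.raises(UndefinedScoreError):
            collapse_proportion(geno, "G")


class TestMadsenBrowningWeights:
    def test_closed_forms(self):
        # w = 1/sqrt(n q (1-q)) without stabilization
        assert madsen_browning_weights(np.array([0.5]), 1, stabilize=False)[0] == pytest.approx(2.0)
        w = madsen_browning_weights(np.array([0.05]), 100, stabilize=False)[0]
        assert w == pytest.approx(1 / np.sqrt(100 * 0.05 * 0.95), abs=1e-10)
        assert w == pytest.approx(0.4588, abs=5e-4)

    def test_monotone_decreasing_in_frequency(self):
        w = madsen_browning_weights(np.array([0.0, 0.001, 0.01, 0.1, 0.5]), 200)
        assert np.all(np.diff(w) < 0)

    def test_stabilization_keeps_monomorphic_finite(self):
        w = madsen_browning_weights(np.array([0.0]), 100)
        assert np.isfinite(w[0]) and w[0] > 0
        # pseudo-count: q~ = 1/(2n+2)
        q = 1 / 202
        assert w[0] == pytest.approx(1 / np.sqrt(100 * q * (1 - q)))


class TestWeightedSumAndCMC:
    def test_weighted_sum_linear_forms(self, tiny_geno):
        s = weighted_sum_score(tiny_geno, "A", weights=np.ones(3))
        assert list(s.values[:5]) == [1, 1, 0, 1, 0]
        s2 = weighted_sum_score(tiny_geno, "A", weights=np.zeros(3))
        assert np.all(s2.values == 0)
        geno = make_genotype_matrix(np.array([[1, 1], [0, 2]]), ["G", "G"])
        s3 = weighted_sum_score(geno, "G", weights=np.array([2.0, 1.0]))
        assert s3.values[0] == pytest.approx(3.0)

    def test_weight_length_mismatch(self, tiny_geno):
        with pytest.raises(ParameterError):
            weighted_sum_score(tiny_geno, "A", weights=np.ones(2))

    def test_cmc_partitions_exactly(self, tiny_geno):
        w = madsen_browning_weights(tiny_geno.maf[tiny_geno.gene_columns("B")],
                                    tiny_geno.n_individuals)
        cmc = cmc_group_scores(tiny_geno, "B", weights=w)
        total = weighted_sum_score(tiny_geno, "B", weights=w)
        # nonsyn + (syn ∪ unknown) columns add up to the all-SNP score exactly
        np.testing.assert_array_equal(cmc.values.sum(axis=1), total.values)

    def test_unknown_annotation_joins_synonymous_group(self, tiny_geno):
        cmc = cmc_group_scores(tiny_geno, "B", weights=np.ones(3))
        # B3 is 'unknown': individual 2 (carries only B3) must score in col 2
        assert cmc.values[1, 1] == 1.0

    def test_all_nonsynonymous_gene_has_zero_syn_column(self, tiny_geno):
        cmc = cmc_group_scores(tiny_geno, "A")
        assert np.all(cmc.values[:, 1] == 0)


class TestBurdenAssociation:
    def test_indicator_equals_thresholded_proportion(self):
        geno = rg.simulate_genotypes(150, 400, seed=3)
        for gene in geno.genes[:30]:
            try:
                prop = collapse_proportion(geno, gene)
            except UndefinedScoreError:
                continue
            ind = collapse_indicator(geno, gene)
            np.testing.assert_array_equal(ind.values, (prop.values > 0).astype(float))

    def test_large_effect_is_detected(self):
        rng = np.random.default_rng(5)
        n = 500
        score = GeneScore(gene="G", values=rng.binomial(1, 0.3, n).astype(float),
                          method="collapse", n_snps_used=3)
        y = 2.0 * score.values + rng.normal(size=n)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        res = fit_burden_association(y, "quantitative", X, score)
        assert res.p_value < 1e-6
        assert res.df == 1

    def test_collinear_score_is_degenerate_not_crash(self):
        rng = np.random.default_rng(6)
        n = 100
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        score = GeneScore(gene="G", values=x.copy(), method="wsum", n_snps_used=1)
        res = fit_burden_association(rng.normal(size=n), "quantitative", X, score)
        assert res.p_value == 1.0
        assert "degenerate" in res.flags and res.df == 0

    def test_constant_score_is_degenerate(self):
        n = 60
        score = GeneScore(gene="G", values=np.zeros(n), method="collapse", n_snps_used=0)
        X = np.ones((n, 1))
        res = fit_burden_association(np.random.default_rng(0).normal(size=n),
                                     "quantitative", X, score)
        assert res.p_value == 1.0 and "degenerate" in res.flags

    def test_lrt_invariant_to_common_weight_scale(self, tiny_geno):
        rng = np.random.default_rng(8)
        y = rng.normal(size=20)
        X = np.ones((20, 1))
        p_vals = []
        for c in (1.0, 7.3, 1e-3):
            s = weighted_sum_score(tiny_geno, "A", weights=np.full(3, c))
            p_vals.append(fit_burden_association(y, "quantitative", X, s).p_value)
        assert p_vals[0] == pytest.approx(p_vals[1], abs=1e-12)
        assert p_vals[0] == pytest.approx(p_vals[2], abs=1e-12)

    def test_binary_separation_falls_back_to_score_test(self):
        # score perfectly predicts y: logistic MLE diverges, Rao fallback kicks in
        n = 40
        y = np.array([1.0] * 20 + [0.0] * 20)
        score = GeneScore(gene="G", values=y.copy(), method="collapse", n_snps_used=1)
        X = np.ones((n, 1))
        res = fit_burden_association(y, "binary", X, score)
        assert "score_fallback" in res.flags
        assert 0.0 <= res.p_value < 0.01

    def test_cmc_drops_empty_group_to_one_df(self, tiny_geno):
        rng = np.random.default_rng(9)
        y = rng.normal(size=20)
        res = fit_burden_association(y, "quantitative", np.ones((20, 1)),
                                     cmc_group_scores(tiny_geno, "A"))
        assert res.df == 1 and "zero_variance_column" in res.flags

    def test_null_cache_matches_direct_call(self, null_cohort):
        geno, cov, pheno = null_cohort
        y = pheno.trait_matrix("q1")[:, 0]
        null = burden_null_cache(y, "quantitative", cov)
        for gene in geno.genes[:10]:
            s = build_score(geno, gene, "wsum")
            a = fit_burden_association(y, "quantitative", cov, s)
            b = fit_burden_association(y, "quantitative", cov, s, null=null)
            assert a.p_value == pytest.approx(b.p_value, abs=1e-12)


class TestScoreProperties:
    """Hypothesis property tests of the score identities."""

    from hypothesis import given, settings, strategies as st
    from hypothesis.extra.numpy import arrays

    @given(arrays(np.int8, (30, 4), elements=st.integers(0, 2)))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_indicator_is_thresholded_proportion_and_cmc_adds_up(self, counts):
        geno = make_genotype_matrix(counts, ["G"] * 4,
                                    annotation=["nonsynonymous", "synonymous",
                                                "nonsynonymous", "unknown"])
        try:
            prop = collapse_proportion(geno, "G")
        except UndefinedScoreError:
            return  # no rare SNPs in this draw: proportion undefined by contract
        ind = collapse_indicator(geno, "G")
        np.testing.assert_array_equal(ind.values, (prop.values > 0).astype(float))
        w = madsen_browning_weights(geno.maf, geno.n_individuals)
        cmc = cmc_group_scores(geno, "G", weights=w)
        total = weighted_sum_score(geno, "G", weights=w)
        np.testing.assert_allclose(cmc.values.sum(axis=1), total.values, rtol=1e-12)
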