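"""IBS-kernel variance-component score test of a gene effect.

Builds weighted and unweighted identity-by-state similarity kernels for one
gene and tests tau = 0 in h ~ N(0, tau K) for a quantitative and a binary
trait, printing Q, the Satterthwaite scale/df and the p-value.
"""
import raregene as rg
from raregene.kernel_tests import ibs_kernel, score_test_binary, score_test_quantitative

geno = rg.simulate_genotypes(697, 2000, seed=21)
cov = rg.simulate_covariates(697, 7, seed=22)
truth = rg.assign_effects(geno, "q2", 10, "maf_linked", seed=23)
truth_b = rg.assign_effects(geno, "affected", 10, "maf_linked", seed=23)
truth.effects.update(truth_b.effects)
truth.architecture.update(truth_b.architecture)
pheno = rg.simulate_phenotypes(geno, cov, truth, R=1, seed=24)

gene = sorted(truth.causal_genes(geno, "q2"))[0]
print(f"testing causal gene {gene} "
      f"({len(geno.gene_columns(gene))} SNPs)")

y = pheno.trait_matrix("q2")[:, 0]
for weighted in (False, True):
    K = ibs_kernel(geno, gene, weighted=weighted)
    res = score_test_quantitative(y, cov, K)
    label = "weighted IBS" if weighted else "unweighted IBS"
    print(f"quantitative, {label:>14}: Q = {res.statistic:8.2f}, "
          f"kappa = {res.kappa:.3f}, nu = {res.nu:.1f}, p = {res.p_value:.2e}")

gene_b = sorted(truth.causal_genes(geno, "affected"))[0]
yb = pheno.trait_matrix("affected")[:, 0]
K = ibs_kernel(geno, gene_b, weighted=True)
res = score_test_binary(yb, cov, K)
print(f"binary,   {'weighted IBS':>14}: Q = {res.statistic:8.2f}, "
      f"kappa = {res.kappa:.3f}, nu = {res.nu:.1f}, p = {res.p_value:.2e}")
# Q is a quadratic form of null-model residuals in the genetic-similarity
# kernel; a small p-value says individuals who are genetically similar at
# this gene are also phenotypically similar after covariate adjustment.
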