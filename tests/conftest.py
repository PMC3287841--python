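import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from raregene.types import CovariateTable, GenotypeMatrix


def make_genotype_matrix(counts, gene_of, annotation=None, snp_ids=None):
    """Build a valid GenotypeMatrix from an explicit count matrix; MAF is the
    empirical frequency so the container invariants hold by construction."""
    counts = np.asarray(counts, dtype=np.int8)
    m = counts.shape[1]
    if snp_ids is None:
        snp_ids = [f"S{j + 1}" for j in range(m)]
    if annotation is None:
        annotation = ["nonsynonymous"] * m
    maf = counts.mean(axis=0) / 2.0
    flip = maf > 0.5
    counts = counts.copy()
    counts[:, flip] = 2 - counts[:, flip]
    maf = np.minimum(maf, 1 - maf)
    return GenotypeMatrix(
        counts=counts,
        snp_ids=np.array(snp_ids, dtype=object),
        gene_of=np.array(gene_of, dtype=object),
        maf=maf,
        annotation=np.array(annotation, dtype=object),
    )


@pytest.fixture
def tiny_geno():
    """20 individuals x 6 SNPs in 2 genes, hand-chosen counts.

    Gene A: three rare nonsynonymous SNPs (single carriers, MAF 0.025);
    gene B: one common SNP B1 (MAF 0.275), one rare synonymous B2, one rare
    unknown B3.  Only the first five rows carry gene A / B2 / B3 alleles.
    """
    counts = np.array([
        # A1 A2 A3 B1 B2 B3
        [0, 0, 1, 0, 0, 0],
        [1, 0, 0, 1, 0, 1],
        [0, 0, 0, 1, 1, 0],
        [0, 1, 0, 1, 0, 0],
        [0, 0, 0, 0, 0, 0],
    ] + [[0, 0, 0, 1, 0, 0]] * 8 + [[0, 0, 0, 0, 0, 0]] * 7)
    return make_genotype_matrix(
        counts,
        gene_of=["A", "A", "A", "B", "B", "B"],
        annotation=["nonsynonymous", "nonsynonymous", "nonsynonymous",
                    "nonsynonymous", "synonymous", "unknown"],
    )


@pytest.fixture
def small_cov():
    rng = np.random.default_rng(42)
    n = 5
    return CovariateTable(pd.DataFrame({
        "age": rng.uniform(20, 70, n),
        "sex": rng.integers(0, 2, n),
        "smoke": rng.integers(0, 2, n),
        "population": ["POP1", "POP2", "POP1", "POP2", "POP1"],
    }))


@pytest.fixture(scope="session")
def null_cohort():
    """Medium null cohort shared by fast distributional tests: 300 individuals,
    ~130 genes, trait independent of all genotypes."""
    import raregene as rg

    geno = rg.simulate_genotypes(300, 1000, seed=901)
    cov = rg.simulate_covariates(300, 4, seed=902)
    truth = rg.assign_effects(geno, "q1", 0, architecture=(0.0, 0.16, 0.84), seed=903)
    pheno = rg.simulate_phenotypes(geno, cov, truth, R=2, seed=904)
    return geno, cov, pheno
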