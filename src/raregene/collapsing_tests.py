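"""Collapsing-based gene-level burden tests.

Four gene scores reduce the SNPs of a gene to one (or two) per-individual
genetic variables g_ik:

* ``collapse`` — carrier indicator: 1 if the individual carries a minor allele
  at any rare SNP (MAF < threshold) of the gene (Li–Leal style).
* ``proportion`` — fraction of the gene's rare SNPs at which the individual
  carries a minor allele (Morris–Zeggini style).
* ``wsum`` — MAF-weighted sum of minor-allele counts over all SNPs of the
  gene (Madsen–Browning style); the weights downweight common variants so no
  hard MAF filter is applied.
* ``cmc`` — two weighted-sum scores, one over nonsynonymous SNPs and one over
  synonymous-or-unknown SNPs, tested jointly (2 df).

Association is tested by regressing the trait on covariates plus the score
column(s) — linear for quantitative traits, logistic for binary — and forming
a likelihood-ratio test that all score coefficients are zero.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from ._glm import LogisticFit, fit_logistic, ols_rss, rao_score_test
from .errors import ParameterError, UndefinedScoreError
from .types import CovariateTable, GeneScore, GeneTestResult, GenotypeMatrix, RARE_MAF

logger = logging.getLogger(__name__)

BURDEN_METHODS = ("collapse", "proportion", "wsum", "cmc")


def _gene_block(
    geno: GenotypeMatrix, gene: str, nonsyn_only: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    cols = geno.gene_columns(gene)
    if nonsyn_only:
        cols = cols[geno.annotation[cols] == "nonsynonymous"]
    return cols, geno.counts[:, cols]


def collapse_indicator(
    geno: GenotypeMatrix,
    gene: str,
    maf_threshold: float = RARE_MAF,
    nonsyn_only: bool = False,
) -> GeneScore:
    """Carrier indicator over the gene's rare SNPs (strictly MAF < threshold)."""
    if not 0.0 < maf_threshold <= 0.5:
        raise ParameterError("maf_threshold must be in (0, 0.5]")
    cols, block = _gene_block(geno, gene, nonsyn_only)
    rare = geno.maf[cols] < maf_threshold
    if not rare.any():
        logger.warning("gene %s has no SNPs with MAF < %g; indicator score is all zero",
                       gene, maf_threshold)
        return GeneScore(gene=gene, values=np.zeros(geno.n_individuals),
                         method="collapse", n_snps_used=0)
    score = (block[:, rare] > 0).any(axis=1).astype(float)
    return GeneScore(gene=gene, values=score, method="collapse",
                     n_snps_used=int(rare.sum()))


def collapse_proportion(
    geno: GenotypeMatrix,
    gene: str,
    maf_threshold: float = RARE_MAF,
    nonsyn_only: bool = False,
    dosage: bool = False,
) -> GeneScore:
    """Proportion of the gene's rare SNPs at which the individual is a carrier.

    With ``dosage=True`` the numerator counts minor alleles (0..2 per SNP)
    instead of carrier presence.
    """
    if not 0.0 < maf_threshold <= 0.5:
        raise ParameterError("maf_threshold must be in (0, 0.5]")
    cols, block = _gene_block(geno, gene, nonsyn_only)
    rare = geno.maf[cols] < maf_threshold
    n_rare = int(rare.sum())
    if n_rare == 0:
        raise UndefinedScoreError(
            f"gene {gene} has no SNPs with MAF < {maf_threshold}; proportion undefined"
        )
    if dosage:
        score = block[:, rare].sum(axis=1) / (2.0 * n_rare)
    else:
        score = (block[:, rare] > 0).sum(axis=1) / n_rare
    return GeneScore(gene=gene, values=score.astype(float), method="proportion",
                     n_snps_used=n_rare)


def madsen_browning_weights(
    maf: np.ndarray, n: int, stabilize: bool = True
) -> np.ndarray:
    """Inverse-sqrt-binomial-variance weights w_l = 1/sqrt(n q~ (1-q~)).

    ``stabilize=True`` replaces q by the add-one allele pseudo-count estimate
    q~ = (2 n q + 1) / (2 n + 2), computed from the full sample, so monomorphic
    SNPs (q = 0) get a finite weight.  Weights decrease strictly in q~.
    """
    maf = np.asarray(maf, dtype=float)
    if n < 1:
        raise ParameterError("need n >= 1")
    if np.any((maf < 0) | (maf > 0.5)):
        raise ParameterError("maf must be in [0, 0.5]")
    q = (2.0 * n * maf + 1.0) / (2.0 * n + 2.0) if stabilize else maf
    if not stabilize and np.any((q <= 0) | (q >= 1)):
        raise ParameterError("unstabilized weights need maf in (0, 0.5]")
    return 1.0 / np.sqrt(n * q * (1.0 - q))


def weighted_sum_score(
    geno: GenotypeMatrix,
    gene: str,
    weights: np.ndarray | None = None,
    nonsyn_only: bool = False,
) -> GeneScore:
    """Weighted sum of minor-allele counts over all SNPs of the gene."""
    cols, block = _gene_block(geno, gene, nonsyn_only)
    if weights is None:
        weights = madsen_browning_weights(geno.maf[cols], geno.n_individuals)
    weights = np.asarray(weights, dtype=float)
    if len(weights) != block.shape[1]:
        raise ParameterError(
            f"gene {gene} has {block.shape[1]} SNPs but {len(weights)} weights given"
        )
    score = block.astype(float) @ weights
    return GeneScore(gene=gene, values=score, method="wsum", n_snps_used=block.shape[1])


def cmc_group_scores(
    geno: GenotypeMatrix,
    gene: str,
    weights: np.ndarray | None = None,
) -> GeneScore:
    """Two weighted-sum scores: nonsynonymous SNPs vs synonymous∪unknown SNPs.

    Ambiguously annotated SNPs are pooled with the synonymous group.  Either
    column may be identically zero when its group is empty.  With shared
    weights the two columns sum exactly to the all-SNP weighted-sum score.
    """
    cols, block = _gene_block(geno, gene, nonsyn_only=False)
    if weights is None:
        weights = madsen_browning_weights(geno.maf[cols], geno.n_individuals)
    weights = np.asarray(weights, dtype=float)
    if len(weights) != block.shape[1]:
        raise ParameterError("weights must align with the gene's SNPs")
    is_ns = geno.annotation[cols] == "nonsynonymous"
    ns = (block[:, is_ns].astype(float) @ weights[is_ns]) if is_ns.any() else np.zeros(geno.n_individuals)
    syn = (block[:, ~is_ns].astype(float) @ weights[~is_ns]) if (~is_ns).any() else np.zeros(geno.n_individuals)
    return GeneScore(
        gene=gene,
        values=np.column_stack([ns, syn]),
        method="cmc",
        columns=("nonsynonymous", "synonymous"),
        n_snps_used=block.shape[1],
    )


@dataclass
class BurdenNull:
    """Cached null-model fit (trait ~ covariates), reusable across genes."""

    trait: np.ndarray
    trait_type: str
    X0: np.ndarray
    rank0: int
    rss0: float | None = None           # quantitative
    logistic: LogisticFit | None = None  # binary


def burden_null_cache(
    trait: np.ndarray, trait_type: str, cov: CovariateTable | np.ndarray
) -> BurdenNull:
    y = np.asarray(trait, dtype=float)
    X0 = cov.design_matrix() if isinstance(cov, CovariateTable) else np.asarray(cov, float)
    if trait_type == "quantitative":
        rss0, rank0 = ols_rss(X0, y)
        return BurdenNull(trait=y, trait_type=trait_type, X0=X0, rank0=rank0, rss0=rss0)
    if trait_type == "binary":
        if not np.all(np.isin(y, [0.0, 1.0])):
            raise ParameterError("binary trait must be coded 0/1")
        fit = fit_logistic(X0, y)
        if not fit.converged or fit.separated:
            fit = fit_logistic(X0, y, ridge=1e-4)
        return BurdenNull(trait=y, trait_type=trait_type, X0=X0,
                          rank0=int(np.linalg.matrix_rank(X0)), logistic=fit)
    raise ParameterError("trait_type must be 'quantitative' or 'binary'")


def fit_burden_association(
    trait: np.ndarray,
    trait_type: str,
    cov: CovariateTable | np.ndarray,
    score: GeneScore,
    null: BurdenNull | None = None,
) -> GeneTestResult:
    """Likelihood-ratio test that all score coefficients are zero, adjusting
    for covariates.

    Score columns with zero variance are dropped (df reduced); a score that is
    collinear with the covariates contributes no rank and is likewise absorbed
    into df.  If nothing testable remains the result is degenerate with
    p = 1.  Non-convergent logistic alternatives (separation) fall back to a
    Rao score test at the null fit, flagged ``score_fallback``.
    """
    if null is None:
        null = burden_null_cache(trait, trait_type, cov)
    y, X0 = null.trait, null.X0
    n = len(y)
    Z = score.as_matrix()
    if Z.shape[0] != n:
        raise ParameterError("score length does not match trait length")
    flags: list[str] = []
    keep = Z.std(axis=0) > 0
    if not keep.all():
        flags.append("zero_variance_column")
    Z = Z[:, keep]
    if Z.shape[1] == 0:
        return GeneTestResult(gene=score.gene, method=score.method, statistic=0.0,
                              p_value=1.0, n_snps_used=score.n_snps_used, df=0,
                              flags=tuple(flags + ["degenerate"]))
    X1 = np.column_stack([X0, Z])

    if null.trait_type == "quantitative":
        rss1, rank1 = ols_rss(X1, y)
        df = rank1 - null.rank0
        if df == 0:
            return GeneTestResult(gene=score.gene, method=score.method, statistic=0.0,
                                  p_value=1.0, n_snps_used=score.n_snps_used, df=0,
                                  flags=tuple(flags + ["collinear", "degenerate"]))
        if df < Z.shape[1]:
            flags.append("collinear")
        lrt = n * np.log(max(null.rss0, 1e-300) / max(rss1, 1e-300))
        lrt = max(lrt, 0.0)
        p = float(chi2.sf(lrt, df))
        return GeneTestResult(gene=score.gene, method=score.method, statistic=float(lrt),
                              p_value=p, n_snps_used=score.n_snps_used, df=df,
                              flags=tuple(flags))

    # binary trait: logistic LRT with warm start from the null fit
    fit0 = null.logistic
    df_full = int(np.linalg.matrix_rank(X1)) - null.rank0
    if df_full == 0:
        return GeneTestResult(gene=score.gene, method=score.method, statistic=0.0,
                              p_value=1.0, n_snps_used=score.n_snps_used, df=0,
                              flags=tuple(flags + ["collinear", "degenerate"]))
    if df_full < Z.shape[1]:
        flags.append("collinear")
    beta0 = np.concatenate([fit0.beta, np.zeros(Z.shape[1])])
    fit1 = fit_logistic(X1, y, beta0=beta0)
    if fit1.converged and not fit1.separated and not fit0.separated:
        lrt = max(2.0 * (fit1.loglik - fit0.loglik), 0.0)
        p = float(chi2.sf(lrt, df_full))
        return GeneTestResult(gene=score.gene, method=score.method, statistic=float(lrt),
                              p_value=p, n_snps_used=score.n_snps_used, df=df_full,
                              flags=tuple(flags))
    stat, df = rao_score_test(X0, Z, y, fit0.mu)
    flags.append("score_fallback")
    if df == 0:
        return GeneTestResult(gene=score.gene, method=score.method, statistic=0.0,
                              p_value=1.0, n_snps_used=score.n_snps_used, df=0,
                              flags=tuple(flags + ["degenerate"]))
    return GeneTestResult(gene=score.gene, method=score.method, statistic=float(stat),
                          p_value=float(chi2.sf(stat, df)), n_snps_used=score.n_snps_used,
                          df=df, flags=tuple(flags))


def build_score(
    geno: GenotypeMatrix,
    gene: str,
    method: str,
    maf_threshold: float = RARE_MAF,
    nonsyn_only: bool = False,
) -> GeneScore:
    """Dispatch to the score constructor for ``method``.

    The CMC score partitions by annotation, so ``nonsyn_only`` does not apply
    to it (its nonsynonymous column already is the nonsynonymous-only score).
    """
    if method == "collapse":
        return collapse_indicator(geno, gene, maf_threshold, nonsyn_only)
    if method == "proportion":
        return collapse_proportion(geno, gene, maf_threshold, nonsyn_only)
    if method == "wsum":
        return weighted_sum_score(geno, gene, nonsyn_only=nonsyn_only)
    if method == "cmc":
        if nonsyn_only:
            s = weighted_sum_score(geno, gene, nonsyn_only=True)
            return GeneScore(gene=gene, values=s.values, method="cmc_ns",
                             n_snps_used=s.n_snps_used)
        return cmc_group_scores(geno, gene)
    raise ParameterError(f"unknown burden method: {method!r}")


__all__ = [
    "BURDEN_METHODS", "GeneScore", "BurdenNull",
    "collapse_indicator", "collapse_proportion", "madsen_browning_weights",
    "weighted_sum_score", "cmc_group_scores", "burden_null_cache",
    "fit_burden_association", "build_score",
]
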