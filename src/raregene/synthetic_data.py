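"""Mini-exome style synthetic data generator.

Emulates the structure of a rare-variant association study on unrelated
individuals: ~87% of SNPs rare (MAF < 5%), genes of heterogeneous size,
nonsynonymous-only causal variants, fixed genotypes with phenotypes re-drawn
per replicate, and (optionally) noncausal SNPs injected as exact genotype
copies of causal SNPs ("genotype twins") to reproduce the collision-driven
false-positive mechanism.

Genotypes are drawn per SNP as Binomial(2, q) independently across individuals
(Hardy-Weinberg proportions, no linkage disequilibrium); twin injection is the
sole source of perfectly correlated SNPs.
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .errors import ParameterError, StateError
from .types import CovariateTable, GenotypeMatrix, PhenotypeSet, SimTruth, TRAITS

# Variance architectures (genetic, environmental, residual) for the
# quantitative traits: Q1 both genetic and environmental, Q2 mostly genetic,
# Q4 environmental only.  For the binary trait the first two entries are
# variance scales of the genetic and environmental parts on the logit scale.
DEFAULT_ARCHITECTURES: dict[str, tuple[float, float, float]] = {
    "q1": (0.206, 0.161, 0.633),
    "q2": (0.124, 0.008, 0.868),
    "q4": (0.0, 0.787, 0.213),
    "affected": (0.5, 0.5, 0.0),
}

#: fraction of SNPs with MAF < 0.05 in the mini-exome being emulated
DEFAULT_RARE_FRACTION = 21355 / 24487  # = 0.8721

DEFAULT_MAF_DIST = {
    "kind": "rare_common_mixture",
    "rare_weight": DEFAULT_RARE_FRACTION,
    # q = 0.05 * Beta(a, b) on the rare side; calibrated so ~39% of rare SNPs
    # fall below the expected-singleton frequency 1/(2*697), matching the
    # singleton-heavy site-frequency spectrum of a mini-exome
    "rare_beta": (0.3, 2.5),
    "common_beta": (0.8, 2.5),   # q = 0.05 + 0.45 * Beta(a, b) on the common side
}

DEFAULT_GENE_SIZE_DIST = {"kind": "nbinom", "mean": 7.6, "shape": 0.9}

DEFAULT_ANNOTATION_PROBS = {"nonsynonymous": 0.62, "synonymous": 0.31, "unknown": 0.07}

DEFAULT_PREVALENCE = 0.30


def _draw_maf(maf_dist: dict, m: int, rng: np.random.Generator) -> np.ndarray:
    kind = maf_dist.get("kind", "rare_common_mixture")
    if kind == "rare_common_mixture":
        w = float(maf_dist.get("rare_weight", DEFAULT_RARE_FRACTION))
        if not 0.0 <= w <= 1.0:
            raise ParameterError("rare_weight must be in [0, 1]")
        a_r, b_r = maf_dist.get("rare_beta", DEFAULT_MAF_DIST["rare_beta"])
        a_c, b_c = maf_dist.get("common_beta", DEFAULT_MAF_DIST["common_beta"])
        rare = rng.random(m) < w
        q = np.empty(m)
        q[rare] = 0.05 * rng.beta(a_r, b_r, size=int(rare.sum()))
        q[~rare] = 0.05 + 0.45 * rng.beta(a_c, b_c, size=int((~rare).sum()))
        return q
    if kind == "beta":
        a, b = maf_dist["a"], maf_dist["b"]
        lo = float(maf_dist.get("low", 0.0))
        hi = float(maf_dist.get("high", 0.5))
        if not (0.0 <= lo < hi <= 0.5):
            raise ParameterError("beta maf_dist bounds must satisfy 0 <= low < high <= 0.5")
        return lo + (hi - lo) * rng.beta(a, b, size=m)
    if kind == "point":
        q = float(maf_dist["value"])
        if not 0.0 < q <= 0.5:
            raise ParameterError("point maf must be in (0, 0.5]")
        return np.full(m, q)
    raise ParameterError(f"unknown maf_dist kind: {kind!r}")


def _draw_gene_sizes(gene_size_dist: dict, m: int, rng: np.random.Generator) -> list[int]:
    kind = gene_size_dist.get("kind", "nbinom")
    sizes: list[int] = []
    total = 0
    if kind == "nbinom":
        mean = float(gene_size_dist.get("mean", 7.6))
        shape = float(gene_size_dist.get("shape", 0.9))
        if mean <= 1 or shape <= 0:
            raise ParameterError("nbinom gene sizes need mean > 1 and shape > 0")
        # sizes are 1 + NB(shape, p) so every gene has at least one SNP
        p = shape / (shape + mean - 1.0)
        while total < m:
            s = 1 + int(rng.negative_binomial(shape, p))
            sizes.append(s)
            total += s
    elif kind == "fixed":
        s = int(gene_size_dist["size"])
        if s < 1:
            raise ParameterError("fixed gene size must be >= 1")
        while total < m:
            sizes.append(s)
            total += s
    else:
        raise ParameterError(f"unknown gene_size_dist kind: {kind!r}")
    sizes[-1] -= total - m  # truncate the last gene to hit exactly m SNPs
    if sizes[-1] == 0:
        sizes.pop()
    return sizes


def simulate_genotypes(
    n: int,
    m: int,
    gene_size_dist: dict | None = None,
    maf_dist: dict | None = None,
    rare_fraction_target: float = DEFAULT_RARE_FRACTION,
    annotation_probs: dict | None = None,
    seed: int = 0,
) -> GenotypeMatrix:
    """Draw an n-individual, m-SNP genotype matrix under Hardy-Weinberg.

    Per-SNP minor-allele counts are Binomial(2, q) with q drawn from
    ``maf_dist`` (default: a rare/common mixture calibrated so ~87% of SNPs
    have MAF < 0.05).  SNPs are packed into genes of heterogeneous size.
    Monomorphic columns (no carriers in the sample) are retained.  Stored MAF
    is the empirical minor-allele frequency of the column; columns whose
    sampled allele ends up with frequency > 0.5 are flipped so counts always
    count the minor allele.
    """
    if n < 2 or m < 1:
        raise ParameterError("need n >= 2 individuals and m >= 1 SNPs")
    rng = np.random.default_rng(seed)
    maf_dist = dict(DEFAULT_MAF_DIST if maf_dist is None else maf_dist)
    if "rare_weight" not in maf_dist and maf_dist.get("kind", "rare_common_mixture") == "rare_common_mixture":
        maf_dist["rare_weight"] = rare_fraction_target
    gene_size_dist = DEFAULT_GENE_SIZE_DIST if gene_size_dist is None else gene_size_dist
    annotation_probs = DEFAULT_ANNOTATION_PROBS if annotation_probs is None else annotation_probs

    q = _draw_maf(maf_dist, m, rng)
    counts = rng.binomial(2, q[None, :], size=(n, m)).astype(np.int8)
    freq = counts.mean(axis=0) / 2.0
    flip = freq > 0.5
    if flip.any():
        counts[:, flip] = 2 - counts[:, flip]
        freq = counts.mean(axis=0) / 2.0
    sizes = _draw_gene_sizes(gene_size_dist, m, rng)
    gene_of = np.concatenate(
        [np.repeat(f"GENE{g + 1:05d}", s) for g, s in enumerate(sizes)]
    ).astype(object)
    labels = list(annotation_probs)
    probs = np.array([annotation_probs[a] for a in labels], dtype=float)
    annotation = rng.choice(labels, size=m, p=probs / probs.sum()).astype(object)
    snp_ids = np.array([f"SNP{j + 1:06d}" for j in range(m)], dtype=object)
    return GenotypeMatrix(
        counts=counts, snp_ids=snp_ids, gene_of=gene_of, maf=freq, annotation=annotation
    )


def simulate_covariates(n: int, n_populations: int = 7, seed: int = 0) -> CovariateTable:
    """Draw the environmental covariate table: Age ~ clipped normal,
    Sex/Smoke ~ Bernoulli, Population ~ near-uniform categorical."""
    if n < 1 or n_populations < 1:
        raise ParameterError("need n >= 1 and n_populations >= 1")
    rng = np.random.default_rng(seed)
    age = np.clip(rng.normal(48.0, 12.0, size=n), 18.0, 90.0)
    sex = rng.integers(0, 2, size=n)
    smoke = (rng.random(n) < 0.25).astype(int)
    population = np.array([f"POP{p + 1}" for p in rng.integers(0, n_populations, size=n)], dtype=object)
    return CovariateTable(pd.DataFrame({"age": age, "sex": sex, "smoke": smoke, "population": population}))


def assign_effects(
    geno: GenotypeMatrix,
    trait: str,
    n_causal_genes: int,
    effect_model: str = "maf_linked",
    effect_scale: float = 1.0,
    snps_per_gene_prob: float = 0.4,
    architecture: tuple[float, float, float] | None = None,
    nonsynonymous_only: bool = True,
    causal_maf_max: float = 0.05,
    min_gene_snps: int = 1,
    sign_negative_prob: float = 0.0,
    seed: int = 0,
) -> SimTruth:
    """Choose causal genes/SNPs and assign per-allele effect sizes.

    ``maf_linked`` sets |beta_l| = effect_scale * |log10(q_l)| so rarer
    variants get larger effects; ``maf_independent`` draws |beta_l| from an
    exponential distribution (mean ``effect_scale``) independent of MAF, a
    heterogeneous-magnitude architecture.  Causal SNPs are sampled only from
    nonsynonymous, polymorphic SNPs with MAF < ``causal_maf_max`` by default —
    a rare-variant architecture (set ``causal_maf_max=0.5`` to allow common
    causal variants).  ``min_gene_snps`` restricts causal-gene eligibility to
    genes with at least that many eligible SNPs (causal genes in exome
    simulations are typically sizeable genes); each eligible SNP of a chosen
    gene becomes causal with probability ``snps_per_gene_prob`` (at least
    one).  The whole effect vector is then rescaled so the population
    variance of the genetic component ``sum_l beta_l * count_il`` equals the
    architecture's genetic fraction (phenotypes are generated on a
    total-variance-1 scale).
    """
    if trait not in TRAITS:
        raise ParameterError(f"trait must be one of {TRAITS}, got {trait!r}")
    if effect_model not in ("maf_linked", "maf_independent"):
        raise ParameterError("effect_model must be 'maf_linked' or 'maf_independent'")
    rng = np.random.default_rng(seed)
    arch = DEFAULT_ARCHITECTURES[trait] if architecture is None else tuple(architecture)
    if arch[0] + arch[1] > 1.0 + 1e-12 and trait != "affected":
        raise ParameterError("genetic + environmental variance fractions exceed 1")

    eligible = (geno.maf > 0) & (geno.maf < causal_maf_max)
    if nonsynonymous_only:
        eligible &= geno.annotation == "nonsynonymous"
    genes_u, counts_u = np.unique(geno.gene_of[eligible].astype(str), return_counts=True)
    eligible_genes = sorted(genes_u[counts_u >= min_gene_snps])
    if n_causal_genes > len(eligible_genes) and min_gene_snps > 1:
        # not enough large genes in this draw: relax the size floor
        eligible_genes = sorted(genes_u)
    if n_causal_genes > len(eligible_genes):
        raise ParameterError(
            f"n_causal_genes={n_causal_genes} exceeds the {len(eligible_genes)} "
            "genes with eligible SNPs"
        )
    truth = SimTruth(architecture={trait: arch})
    if n_causal_genes == 0:
        truth.effects[trait] = pd.Series(dtype=float)
        if trait != "affected" and arch[0] != 0.0:
            raise ParameterError("nonzero genetic fraction requires causal genes")
        return truth

    chosen = rng.choice(eligible_genes, size=n_causal_genes, replace=False)
    causal_idx: list[int] = []
    for g in chosen:
        cand = np.flatnonzero((geno.gene_of == g) & eligible)
        take = cand[rng.random(len(cand)) < snps_per_gene_prob]
        if len(take) == 0:
            take = cand[[rng.integers(len(cand))]]
        causal_idx.extend(take.tolist())
    causal_idx = sorted(causal_idx)
    q = geno.maf[causal_idx]

    if effect_model == "maf_linked":
        beta = effect_scale * np.abs(np.log10(q))
    else:
        beta = rng.exponential(effect_scale, size=len(causal_idx))
    sign = np.where(rng.random(len(beta)) < sign_negative_prob, -1.0, 1.0)
    beta = beta * sign

    target_vg = arch[0]
    if target_vg > 0:
        genetic = geno.counts[:, causal_idx].astype(float) @ beta
        v = genetic.var()
        if v <= 0:
            raise StateError("causal genotypes carry no variance; cannot scale effects")
        beta = beta * math.sqrt(target_vg / v)
    else:
        beta = np.zeros_like(beta)
    truth.effects[trait] = pd.Series(beta, index=[geno.snp_ids[j] for j in causal_idx])
    return truth


def _genetic_component(geno: GenotypeMatrix, truth: SimTruth, trait: str) -> np.ndarray:
    eff = truth.effects.get(trait)
    if eff is None or len(eff) == 0:
        return np.zeros(geno.n_individuals)
    idx = [geno.snp_index(s) for s in eff.index]
    return geno.counts[:, idx].astype(float) @ eff.to_numpy()


def _environmental_component(
    cov: CovariateTable, target_var: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed covariate effect scaled so its population variance is target_var."""
    X = cov.design_matrix(add_intercept=False)
    p = X.shape[1]
    gamma = rng.normal(0.0, 1.0, size=p) / np.maximum(X.std(axis=0), 1e-12)
    env = X @ gamma
    v = env.var()
    if target_var == 0.0 or v <= 0:
        return np.zeros(len(env)), np.zeros(p)
    scale = math.sqrt(target_var / v)
    return env * scale, gamma * scale


def simulate_phenotypes(
    geno: GenotypeMatrix,
    cov: CovariateTable,
    truth: SimTruth,
    R: int = 200,
    prevalence: float = DEFAULT_PREVALENCE,
    seed: int = 0,
) -> PhenotypeSet:
    """Draw R phenotype replicates on the fixed genotypes and covariates.

    Quantitative traits: y_ik = sum_l beta_l c_il + gamma' X_i + e_ik with
    e_ik ~ N(0, residual fraction); the genetic and environmental components
    are rescaled to their architecture fractions (total variance ~= 1) and are
    identical across replicates — only the noise is re-drawn.  The binary
    trait is drawn from logit P(affected) = b0 + genetic + environmental with
    b0 solved by root-finding so the expected prevalence matches.

    Traits without an entry in ``truth.effects``/``truth.architecture`` are
    generated as pure pseudo-trait noise columns so every replicate table has
    the full (affected, q1, q2, q4) layout.
    """
    if R < 1:
        raise ParameterError("need R >= 1 replicates")
    if not 0.0 < prevalence < 1.0:
        raise ParameterError("prevalence must be in (0, 1)")
    if geno.n_individuals != cov.n_individuals:
        raise ParameterError("genotypes and covariates disagree on n")
    n = geno.n_individuals
    root = np.random.SeedSequence(seed)
    comp_rng = np.random.default_rng(root.spawn(1)[0])

    fixed: dict[str, np.ndarray] = {}
    resid_sd: dict[str, float] = {}
    logit_fixed: np.ndarray | None = None
    for trait in TRAITS:
        arch = truth.architecture.get(trait)
        if arch is None:
            continue
        genetic = _genetic_component(geno, truth, trait)
        env, _ = _environmental_component(cov, arch[1], comp_rng)
        if trait == "affected":
            part = genetic + env
            b0 = _solve_intercept(part, prevalence)
            logit_fixed = b0 + part
        else:
            fixed[trait] = genetic + env
            resid_sd[trait] = math.sqrt(max(arch[2], 0.0))

    reps: list[pd.DataFrame] = []
    rep_seeds = root.spawn(R)
    for k in range(R):
        rng = np.random.default_rng(rep_seeds[k])
        cols: dict[str, np.ndarray] = {}
        if logit_fixed is not None:
            cols["affected"] = (rng.random(n) < expit(logit_fixed)).astype(int)
        else:
            cols["affected"] = (rng.random(n) < prevalence).astype(int)
        for trait in ("q1", "q2", "q4"):
            if trait in fixed:
                cols[trait] = fixed[trait] + rng.normal(0.0, resid_sd[trait], size=n)
            else:
                cols[trait] = rng.normal(0.0, 1.0, size=n)
        reps.append(pd.DataFrame(cols, columns=["affected", "q1", "q2", "q4"]))
    return PhenotypeSet(replicates=reps)


def _solve_intercept(fixed_logit: np.ndarray, prevalence: float) -> float:
    """Intercept b0 with mean(expit(b0 + fixed)) = prevalence, by brentq."""

    def f(b0: float) -> float:
        return float(expit(b0 + fixed_logit).mean() - prevalence)

    return brentq(f, -30.0, 30.0, xtol=1e-10)


def inject_twins(
    geno: GenotypeMatrix,
    truth: SimTruth,
    n_twins: int,
    trait: str | None = None,
    seed: int = 0,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Overwrite n_twins noncausal SNP columns with exact copies of randomly
    chosen causal SNP columns, recording each pair in ``truth.twin_map``.

    Twins are preferentially placed in genes containing no causal SNP, so the
    injected collisions create spurious gene-level signal (the false-positive
    mechanism in which a noncausal — possibly synonymous — SNP is statistically
    indistinguishable from a causal one).  Annotation of the twin column is
    left unchanged.
    """
    traits = [trait] if trait is not None else [t for t in TRAITS if len(truth.effects.get(t, ())) > 0]
    causal_ids = sorted({s for t in traits for s in truth.causal_snps(t)})
    if not causal_ids:
        raise StateError("cannot inject twins: truth contains no causal SNPs")
    if n_twins == 0:
        return geno, truth
    causal_set = set(causal_ids)
    causal_genes = {geno.gene_of[geno.snp_index(s)] for s in causal_ids}
    noncausal = [j for j, s in enumerate(geno.snp_ids) if s not in causal_set]
    if n_twins > len(noncausal):
        raise ParameterError("n_twins exceeds the number of noncausal SNPs")
    rng = np.random.default_rng(seed)
    preferred = [j for j in noncausal if geno.gene_of[j] not in causal_genes]
    pool = preferred if len(preferred) >= n_twins else noncausal
    targets = rng.choice(pool, size=n_twins, replace=False)
    sources = rng.choice(causal_ids, size=n_twins, replace=True)

    out = geno.copy()
    new_truth = truth.copy()
    for j, src in zip(targets, sources):
        src_col = geno.snp_index(src)
        out.counts[:, j] = geno.counts[:, src_col]
        out.maf[j] = geno.maf[src_col]
        new_truth.twin_map[str(geno.snp_ids[j])] = str(src)
    return out, new_truth


__all__ = [
    "DEFAULT_ARCHITECTURES", "DEFAULT_RARE_FRACTION", "DEFAULT_MAF_DIST",
    "DEFAULT_GENE_SIZE_DIST", "DEFAULT_PREVALENCE",
    "simulate_genotypes", "simulate_covariates", "assign_effects",
    "simulate_phenotypes", "inject_twins",
]
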