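"""Pipeline orchestration: simulate → bayes → test → evaluate.

Each stage reads and writes the TSV formats in :mod:`raregene.io`, derives
its randomness from the master seed + stage name, and records what it did in
``run_log.json``.  The same functions back the command-line interface, but
everything is importable and composable from Python.
"""
from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as rio
from .bayes_mixed import (
    MCMCSettings, MixedModelSpec, gibbs_linear, mcmc_logistic, variance_decomposition,
)
from .collapsing_tests import build_score, burden_null_cache, fit_burden_association
from .config import RunConfig, seed_for
from .errors import ParameterError, StateError, UndefinedScoreError
from .evaluation import find_genotype_twins, maf_effect_correlation, power_typeI, roc_curve
from .kernel_tests import (
    binary_kernel_null, ibs_kernel, quantitative_kernel_null,
    score_test_binary, score_test_quantitative,
)
from .synthetic_data import (
    assign_effects, inject_twins, simulate_covariates, simulate_genotypes,
    simulate_phenotypes,
)
from .types import CovariateTable, GeneTestResult, GenotypeMatrix, results_frame

logger = logging.getLogger(__name__)

ALL_METHODS = ("collapse", "proportion", "wsum", "cmc", "kernel", "wkernel")


def run_gene_tests(
    geno: GenotypeMatrix,
    cov: CovariateTable | np.ndarray | None,
    trait_values: np.ndarray,
    trait_type: str,
    methods: tuple[str, ...] = ALL_METHODS,
    maf_threshold: float = 0.05,
    nonsyn_only: bool = False,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Run gene-level tests for every gene × method × replicate.

    ``trait_values`` is ``(n,)`` for a single phenotype or ``(n, R)`` for R
    replicates; genotypes and covariates are shared across replicates, so
    null-model fits (and, for quantitative kernels, the trace-based null
    moments) are computed once and reused.  Genes a method cannot score
    (e.g. no rare SNP for the proportion score) are skipped with a logged
    reason and do not appear in that method's rows.
    """
    Y = np.asarray(trait_values, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, R = Y.shape
    if genes is None:
        genes = geno.genes
    burden_methods = [m for m in methods if m in ("collapse", "proportion", "wsum", "cmc")]
    kernel_methods = [m for m in methods if m in ("kernel", "wkernel")]
    unknown = set(methods) - set(burden_methods) - set(kernel_methods)
    if unknown:
        raise ParameterError(f"unknown methods: {sorted(unknown)}")

    rows: list[dict] = []
    skipped: list[tuple[str, str, str]] = []

    if burden_methods:
        nulls = [burden_null_cache(Y[:, k], trait_type, cov if cov is not None else np.ones((n, 1)))
                 for k in range(R)]
        for gene in genes:
            for method in burden_methods:
                try:
                    score = build_score(geno, gene, method, maf_threshold, nonsyn_only)
                except UndefinedScoreError as exc:
                    skipped.append((gene, method, str(exc)))
                    logger.info("skipping gene %s for %s: %s", gene, method, exc)
                    continue
                for k in range(R):
                    res = fit_burden_association(Y[:, k], trait_type, cov, score, null=nulls[k])
                    row = res.to_row()
                    row["replicate"] = k + 1
                    rows.append(row)

    if kernel_methods:
        if trait_type == "quantitative":
            nulls_q = [quantitative_kernel_null(Y[:, k], cov) for k in range(R)]
        else:
            nulls_b = [binary_kernel_null(Y[:, k], cov) for k in range(R)]
        for gene in genes:
            for method in kernel_methods:
                try:
                    K = ibs_kernel(geno, gene, weighted=(method == "wkernel"),
                                   nonsyn_only=nonsyn_only)
                except ParameterError as exc:
                    skipped.append((gene, method, str(exc)))
                    logger.info("skipping gene %s for %s: %s", gene, method, exc)
                    continue
                cols = geno.gene_columns(gene)
                if nonsyn_only:
                    cols = cols[geno.annotation[cols] == "nonsynonymous"]
                if trait_type == "quantitative":
                    res0 = _quant_kernel_replicates(K, nulls_q, gene)
                else:
                    res0 = [score_test_binary(Y[:, k], cov, K, null=nulls_b[k])
                            for k in range(R)]
                for k, res in enumerate(res0):
                    res.n_snps_used = len(cols)
                    row = res.to_row()
                    row["replicate"] = k + 1
                    rows.append(row)

    df = pd.DataFrame(rows)
    df.attrs["skipped"] = skipped
    return df


def _quant_kernel_replicates(K, nulls, gene) -> list[GeneTestResult]:
    """Quantitative kernel tests across replicates sharing one design: the
    null moments depend only on the design, so compute them once per gene."""
    from scipy.stats import chi2

    null0 = nulls[0]
    Kv = K.values
    method = "kernel_wibs" if K.weighted else "kernel_ibs"
    KX = Kv @ null0.X
    A = Kv - null0.Xp @ (null0.X.T @ Kv)
    e = 0.5 * (np.trace(Kv) - float(np.sum(null0.Xp * KX)))
    i_tt = 0.5 * float(np.sum(A * A.T))
    var = i_tt - e * e / (0.5 * (null0.n - null0.p))
    out = []
    for null in nulls:
        r = null.resid
        Q = float(r @ (Kv @ r)) / (2.0 * null.sigma2)
        if e <= 1e-12 or var <= 1e-12:
            out.append(GeneTestResult(gene=gene, method=method, statistic=Q,
                                      p_value=1.0, n_snps_used=-1, flags=("degenerate",)))
            continue
        kappa = var / (2.0 * e)
        nu = 2.0 * e * e / var
        out.append(GeneTestResult(gene=gene, method=method, statistic=Q,
                                  p_value=float(chi2.sf(Q / kappa, nu)),
                                  n_snps_used=-1, kappa=kappa, nu=nu))
    return out


# ---------------------------------------------------------------------------
# pipeline stages

def _paths(config: RunConfig) -> dict[str, Path]:
    d = Path(config.out_dir)
    return {
        "dir": d,
        "genotypes": d / "genotypes.tsv",
        "snps": d / "snps.tsv",
        "covariates": d / "covariates.tsv",
        "pheno": d / "pheno",
        "truth": d / "truth.tsv",
        "twins": d / "twins.tsv",
        "vardecomp": d / "vardecomp.tsv",
        "log": d / "run_log.json",
    }


def _log_stage(config: RunConfig, stage: str, extra: dict | None = None) -> None:
    p = _paths(config)["log"]
    log = json.loads(p.read_text()) if p.exists() else {
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "version": __version__,
        "stages": {},
    }
    log["stages"][stage] = {
        "seed": seed_for(config.master_seed, stage),
        "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
        **(extra or {}),
    }
    p.parent.mkdir(parents=True, exist_ok=True)
    p.write_text(json.dumps(log, indent=2))


def stage_simulate(config: RunConfig) -> None:
    """Generate genotypes, covariates, causal truth and phenotype replicates."""
    config.validate()
    p = _paths(config)
    p["dir"].mkdir(parents=True, exist_ok=True)
    geno = simulate_genotypes(
        config.n, config.m, rare_fraction_target=config.rare_fraction_target,
        seed=seed_for(config.master_seed, "genotypes"),
    )
    cov = simulate_covariates(config.n, config.n_populations,
                              seed=seed_for(config.master_seed, "covariates"))
    truth = None
    for trait, tc in config.traits.items():
        t = assign_effects(
            geno, trait, tc.n_causal_genes, tc.effect_model, tc.effect_scale,
            architecture=tc.architecture,
            seed=seed_for(config.master_seed, f"effects_{trait}"),
        )
        if truth is None:
            truth = t
        else:
            truth.effects.update(t.effects)
            truth.architecture.update(t.architecture)
    if config.n_twins > 0:
        geno, truth = inject_twins(geno, truth, config.n_twins,
                                   seed=seed_for(config.master_seed, "twins"))
    pheno = simulate_phenotypes(geno, cov, truth, R=config.R,
                                prevalence=config.prevalence,
                                seed=seed_for(config.master_seed, "phenotypes"))
    rio.write_genotypes(geno, p["genotypes"], p["snps"])
    rio.write_covariates(cov, p["covariates"])
    rio.write_phenotypes(pheno, p["pheno"])
    rio.write_truth(truth, p["truth"], p["twins"])
    _log_stage(config, "simulate", {"n": config.n, "m": config.m, "R": config.R})


def _load_inputs(config: RunConfig):
    p = _paths(config)
    for key in ("genotypes", "snps", "covariates"):
        if not p[key].exists():
            raise StateError(f"missing input {p[key]}; run the simulate stage first")
    geno = rio.read_genotypes(p["genotypes"], "tsv", p["snps"])
    cov = rio.read_covariates(p["covariates"])
    pheno = rio.read_phenotypes(p["pheno"])
    return geno, cov, pheno


def stage_bayes(config: RunConfig, trait: str) -> None:
    """Fit the Bayesian mixed-effects model for one trait; write the posterior
    genetic effects and the variance decomposition row."""
    p = _paths(config)
    geno, cov, pheno = _load_inputs(config)
    Y = pheno.trait_matrix(trait)
    X = cov.design_matrix()
    mcmc = MCMCSettings(iterations=config.mcmc_iterations, burn_in=config.mcmc_burn_in,
                        thin=config.mcmc_thin, seed=seed_for(config.master_seed, f"bayes_{trait}"))
    spec = MixedModelSpec(responses=Y, design=X, mcmc=mcmc)
    if trait == "affected":
        post = mcmc_logistic(spec)
    else:
        post = gibbs_linear(spec)
    if Y.shape[1] == 1:
        logger.warning("bayes stage with a single replicate: posteriors will be wide")
    vd = variance_decomposition(post, X)
    out = pd.DataFrame({
        "individual_id": [f"IND{i + 1:05d}" for i in range(post.n_individuals)],
        "g_mean": post.g_mean, "g_sd": post.g_sd,
    })
    out.to_csv(p["dir"] / f"posterior_{trait}.tsv", sep="\t", index=False)
    row = pd.DataFrame([{
        "trait": trait, "prop_genetic": vd.prop_genetic,
        "prop_environmental": vd.prop_environmental,
        "prop_residual": vd.prop_residual,
    }])
    if p["vardecomp"].exists():
        old = pd.read_csv(p["vardecomp"], sep="\t")
        row = pd.concat([old[old["trait"] != trait], row], ignore_index=True)
    row.to_csv(p["vardecomp"], sep="\t", index=False)
    _log_stage(config, f"bayes_{trait}",
               {"diagnostics": {k: float(v) for k, v in post.diagnostics.items()}})


def stage_test(config: RunConfig, trait: str,
               methods: tuple[str, ...] | None = None,
               nonsyn_only: bool | None = None) -> None:
    """Run all configured gene-level tests for one trait across replicates."""
    p = _paths(config)
    geno, cov, pheno = _load_inputs(config)
    methods = config.methods if methods is None else methods
    nonsyn_only = config.nonsyn_only if nonsyn_only is None else nonsyn_only
    Y = pheno.trait_matrix(trait)
    trait_type = "binary" if trait == "affected" else "quantitative"
    df = run_gene_tests(geno, cov, Y, trait_type, methods,
                        maf_threshold=config.maf_threshold, nonsyn_only=nonsyn_only)
    suffix = "_ns" if nonsyn_only else ""
    rio.write_results(df, p["dir"] / f"results_{trait}{suffix}.tsv")
    skip_rows = pd.DataFrame(df.attrs.get("skipped", []),
                             columns=["gene", "method", "reason"])
    skip_rows.to_csv(p["dir"] / f"skipped_{trait}{suffix}.tsv", sep="\t", index=False)
    _log_stage(config, f"test_{trait}{suffix}",
               {"methods": list(methods), "n_tests": len(df), "n_skipped": len(skip_rows)})


def stage_evaluate(config: RunConfig, trait: str, alpha: float | None = None) -> None:
    """ROC, AUC, power/type-I and collision diagnostics for one trait."""
    p = _paths(config)
    alpha = config.alpha if alpha is None else alpha
    res_path = p["dir"] / f"results_{trait}.tsv"
    if not res_path.exists():
        raise StateError(f"missing results file {res_path}; run the test stage first")
    if not p["truth"].exists():
        raise StateError(f"missing truth file {p['truth']}; run the simulate stage first")
    results = rio.read_results(res_path)
    truth = rio.read_truth(p["truth"], p["twins"])
    geno = rio.read_genotypes(p["genotypes"], "tsv", p["snps"])
    causal_genes = truth.causal_genes(geno, trait)
    roc_rows, auc_rows, power_rows = [], [], []
    for method in sorted(results["method"].unique()):
        roc = roc_curve(results, causal_genes, method=method)
        for t, tp, fp in zip(roc.thresholds, roc.tpr, roc.fpr):
            roc_rows.append({"method": method, "threshold": t, "tpr": tp, "fpr": fp})
        auc_rows.append({"method": method, "auc": roc.auc})
        pw, t1 = power_typeI(results, causal_genes, alpha, method=method)
        power_rows.append({"method": method, "alpha": alpha, "power": pw, "type_i": t1})
    pd.DataFrame(roc_rows).to_csv(p["dir"] / f"roc_{trait}.tsv", sep="\t", index=False)
    pd.DataFrame(auc_rows).to_csv(p["dir"] / f"auc_{trait}.tsv", sep="\t", index=False)
    pd.DataFrame(power_rows).to_csv(p["dir"] / f"power_{trait}.tsv", sep="\t", index=False)
    causal_snps = set(truth.causal_snps(trait))
    if causal_snps:
        rep = find_genotype_twins(geno, causal_snps)
        pd.DataFrame(rep.pairs, columns=["noncausal_snp", "causal_snp"]).to_csv(
            p["dir"] / f"collisions_{trait}.tsv", sep="\t", index=False)
    try:
        r, pv = maf_effect_correlation(truth, geno, trait)
        corr = {"trait": trait, "r": r, "p": pv}
    except Exception:
        corr = {"trait": trait, "r": float("nan"), "p": float("nan")}
    pd.DataFrame([corr]).to_csv(p["dir"] / f"maf_effect_{trait}.tsv", sep="\t", index=False)
    _log_stage(config, f"evaluate_{trait}", {"alpha": alpha})


def run_pipeline(config: RunConfig) -> int:
    """Run every stage end to end; returns 0 on success."""
    config.validate()
    stage_simulate(config)
    for trait in config.test_traits:
        stage_bayes(config, trait)
        stage_test(config, trait)
        stage_evaluate(config, trait)
    return 0


__all__ = ["ALL_METHODS", "run_gene_tests", "stage_simulate", "stage_bayes",
           "stage_test", "stage_evaluate", "run_pipeline"]
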