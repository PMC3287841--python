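"""Method comparison across replicates: ROC curves, power / type-I error,
genotype-collision diagnostics, and MAF–effect-size / score correlations.

Gene-level labeling: a gene is *causal* for a trait iff it contains at least
one causal SNP for that trait.  Noncausal genes that harbor a genotype twin
of a causal SNP remain labeled noncausal — detecting them is precisely the
false-positive mechanism these diagnostics quantify.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .errors import ParameterError, UndefinedStatisticError
from .types import GeneScore, GenotypeMatrix, SimTruth


@dataclass
class ROCResult:
    method: str
    thresholds: np.ndarray  # ascending p-value cutoffs
    tpr: np.ndarray         # nondecreasing along thresholds
    fpr: np.ndarray
    auc: float


@dataclass
class CollisionReport:
    """Noncausal SNPs whose genotype column exactly equals >= 1 causal SNP's."""

    pairs: list[tuple[str, str]]   # (noncausal snp, causal snp)
    n_colliding_snps: int

    def colliding_snps(self) -> set[str]:
        return {a for a, _ in self.pairs}


def _extract(results: pd.DataFrame, method: str | None) -> pd.DataFrame:
    if method is not None and "method" in results.columns:
        results = results[results["method"] == method]
    if results.empty:
        raise ParameterError("no test results for the requested method")
    return results


def roc_curve(
    results: pd.DataFrame,
    causal_genes: set[str],
    method: str | None = None,
) -> ROCResult:
    """ROC over pooled gene-replicate tests.

    ``results`` needs columns ``gene`` and ``p_value`` (and optionally
    ``method``); every row is one gene-replicate test.  At each threshold t,
    tpr(t) is the fraction of causal rows with p <= t, fpr(t) the same for
    noncausal rows; thresholds are the distinct p-values, and the AUC is the
    trapezoid area (equal to the tie-corrected Mann-Whitney probability).
    """
    results = _extract(results, method)
    p = results["p_value"].to_numpy(float)
    is_causal = results["gene"].isin(causal_genes).to_numpy()
    n_pos = int(is_causal.sum())
    n_neg = int(len(p) - n_pos)
    if n_pos == 0:
        raise UndefinedStatisticError("no causal genes among the tested genes")
    if n_neg == 0:
        raise UndefinedStatisticError("no noncausal genes among the tested genes")
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    causal_sorted = is_causal[order]
    thresholds, last_idx = np.unique(p_sorted, return_index=True)
    # cumulative counts at each distinct threshold (p <= t)
    cum_pos = np.cumsum(causal_sorted)
    cum_neg = np.cumsum(~causal_sorted)
    idx = np.searchsorted(p_sorted, thresholds, side="right") - 1
    tpr = cum_pos[idx] / n_pos
    fpr = cum_neg[idx] / n_neg
    fpr_full = np.concatenate([[0.0], fpr])
    tpr_full = np.concatenate([[0.0], tpr])
    auc = float(np.trapezoid(tpr_full, fpr_full))
    label = method if method is not None else (
        results["method"].iloc[0] if "method" in results.columns else "unknown")
    return ROCResult(method=label, thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


def power_typeI(
    results: pd.DataFrame,
    causal_genes: set[str],
    alpha: float,
    method: str | None = None,
) -> tuple[float, float]:
    """(power, type-I error) at level alpha over pooled gene-replicate tests."""
    results = _extract(results, method)
    p = results["p_value"].to_numpy(float)
    is_causal = results["gene"].isin(causal_genes).to_numpy()
    n_pos, n_neg = int(is_causal.sum()), int((~is_causal).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedStatisticError("need both causal and noncausal genes")
    sig = p <= alpha
    return float(sig[is_causal].mean()), float(sig[~is_causal].mean())


def find_genotype_twins(
    geno: GenotypeMatrix, causal_snps: set[str] | list[str]
) -> CollisionReport:
    """Every noncausal SNP whose count column is elementwise identical to at
    least one causal SNP's column.

    Columns are bucketed by a byte hash and verified by exact comparison, so
    the result equals the brute-force all-pairs scan.
    """
    causal = list(dict.fromkeys(causal_snps))
    if not causal:
        raise ParameterError("causal SNP set must be nonempty")
    causal_set = set(causal)
    by_hash: dict[bytes, list[str]] = {}
    for s in causal:
        col = np.ascontiguousarray(geno.counts[:, geno.snp_index(s)])
        by_hash.setdefault(col.tobytes(), []).append(s)
    pairs: list[tuple[str, str]] = []
    for j, snp in enumerate(geno.snp_ids):
        if snp in causal_set:
            continue
        key = np.ascontiguousarray(geno.counts[:, j]).tobytes()
        for src in by_hash.get(key, ()):  # hash hit; bytes equality is exact
            pairs.append((str(snp), src))
    return CollisionReport(pairs=pairs, n_colliding_snps=len({a for a, _ in pairs}))


def near_collisions(
    geno: GenotypeMatrix,
    causal_snps: set[str] | list[str],
    min_correlation: float = 0.95,
) -> list[tuple[str, str, float]]:
    """Noncausal SNPs whose column correlates with a causal SNP's column at
    r >= min_correlation but is not identical (the "similar but not exactly
    the same" confounders)."""
    causal = list(dict.fromkeys(causal_snps))
    if not causal:
        raise ParameterError("causal SNP set must be nonempty")
    causal_idx = [geno.snp_index(s) for s in causal]
    C = geno.counts.astype(float)
    Cc = C - C.mean(axis=0)
    sd = Cc.std(axis=0)
    out: list[tuple[str, str, float]] = []
    for s, jc in zip(causal, causal_idx):
        if sd[jc] == 0:
            continue
        ok = sd > 0
        r = np.zeros(geno.n_snps)
        r[ok] = (Cc[:, ok].T @ Cc[:, jc]) / (len(C) * sd[ok] * sd[jc])
        hits = np.flatnonzero((r >= min_correlation) & ok)
        for j in hits:
            snp = str(geno.snp_ids[j])
            if snp in causal or np.array_equal(geno.counts[:, j], geno.counts[:, jc]):
                continue
            out.append((snp, s, float(r[j])))
    return out


def maf_effect_correlation(
    truth: SimTruth, geno: GenotypeMatrix, trait: str
) -> tuple[float, float]:
    """Pearson correlation between causal-SNP MAF and effect size beta, with
    the standard t-based two-sided p-value."""
    eff = truth.effects.get(trait)
    if eff is None or len(eff) < 3:
        raise ParameterError("need >= 3 causal SNPs")
    maf = np.array([geno.maf[geno.snp_index(s)] for s in eff.index])
    beta = eff.to_numpy(float)
    if maf.std() == 0 or beta.std() == 0:
        raise UndefinedStatisticError("constant MAF or constant effect size")
    r, p = pearsonr(maf, beta)
    return float(r), float(p)


def score_correlation(
    score_a: GeneScore | np.ndarray, score_b: GeneScore | np.ndarray
) -> tuple[float, float]:
    """Pearson correlation of two genes' per-individual scores (diagnoses
    confounded gene pairs whose scores are nearly identical)."""
    a = score_a.values if isinstance(score_a, GeneScore) else np.asarray(score_a, float)
    b = score_b.values if isinstance(score_b, GeneScore) else np.asarray(score_b, float)
    a, b = np.asarray(a, float).ravel(), np.asarray(b, float).ravel()
    if a.shape != b.shape:
        raise ParameterError("scores must have equal length")
    if a.std() == 0 or b.std() == 0:
        raise UndefinedStatisticError("constant score has no defined correlation")
    r, p = pearsonr(a, b)
    return float(r), float(p)


def plot_roc(rocs: list[ROCResult], path: str | None = None):
    """Plot one or more ROC curves (requires matplotlib, an optional extra)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for roc in rocs:
        fpr = np.concatenate([[0.0], roc.fpr, [1.0]])
        tpr = np.concatenate([[0.0], roc.tpr, [1.0]])
        ax.plot(fpr, tpr, label=f"{roc.method} (AUC {roc.auc:.3f})")
    ax.plot([0, 1], [0, 1], ls=":", c="gray", lw=1)
    ax.set_xlabel("false-positive rate (noncausal genes)")
    ax.set_ylabel("true-positive rate (causal genes)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


__all__ = [
    "ROCResult", "CollisionReport", "roc_curve", "power_typeI",
    "find_genotype_twins", "near_collisions", "maf_effect_correlation",
    "score_correlation", "plot_roc",
]
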