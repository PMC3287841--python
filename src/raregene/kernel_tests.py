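"""IBS-kernel variance-component score tests.

A gene's genotypes enter through an n × n genetic-similarity matrix built
from identity-by-state (IBS) allele sharing: at SNP l two individuals with
minor-allele counts a, b share IBS(a, b) = 2 − |a − b| alleles.  The weighted
IBS kernel is

    K_ij = sum_l w_l * IBS(c_il, c_jl) / (2 * sum_l w_l),

normalized so K ∈ [0, 1] with K_ii = 1.  Weighting w_l decreasing in MAF
encodes the idea that sharing a rare allele is more informative about trait
similarity than sharing a common one.

The gene effect h is modeled as a random effect h ~ N(0, τK); testing h = 0
reduces to testing the variance component τ = 0 with a quadratic-form score
statistic on null-model residuals (Zhang–Lin).  The null distribution is
approximated by a Satterthwaite scaled chi-square κ·χ²_ν matched to the
statistic's null mean and variance.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from ._glm import fit_logistic
from .collapsing_tests import madsen_browning_weights
from .errors import ParameterError
from .types import CovariateTable, GeneTestResult, GenotypeMatrix

logger = logging.getLogger(__name__)

KERNEL_METHODS = ("kernel_ibs", "kernel_wibs")


@dataclass
class KernelMatrix:
    """Symmetric nonnegative n × n IBS similarity matrix for one gene."""

    values: np.ndarray
    gene: str
    weighted: bool

    @property
    def n(self) -> int:
        return self.values.shape[0]


def ibs_kernel(
    geno: GenotypeMatrix,
    gene: str,
    weights: np.ndarray | None = None,
    weighted: bool = True,
    nonsyn_only: bool = False,
) -> KernelMatrix:
    """Weighted or unweighted IBS kernel over the SNPs of ``gene``.

    ``weights=None`` with ``weighted=True`` uses the stabilized
    Madsen–Browning weights; ``weighted=False`` sets all weights to 1.
    """
    cols = geno.gene_columns(gene)
    if nonsyn_only:
        cols = cols[geno.annotation[cols] == "nonsynonymous"]
    if len(cols) == 0:
        raise ParameterError(f"gene {gene!r} has no SNPs after filtering")
    C = geno.counts[:, cols]
    if weights is None:
        w = (madsen_browning_weights(geno.maf[cols], geno.n_individuals)
             if weighted else np.ones(len(cols)))
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(cols):
            raise ParameterError("weights must align with the gene's SNPs")
        if np.any(w < 0):
            raise ParameterError("kernel weights must be nonnegative")
    wtot = float(w.sum())
    if wtot <= 0:
        raise ParameterError("kernel weights must not be all zero")
    # sum_l w_l * IBS = sum_l w_l * (2 - c_i - c_j + 2*min(c_i, c_j)),
    # and for counts in {0,1,2}: min(a, b) = 1[a>=1]1[b>=1] + 1[a>=2]1[b>=2]
    B1 = (C >= 1).astype(float)
    B2 = (C >= 2).astype(float)
    s = C.astype(float) @ w
    M = (B1 * w) @ B1.T + (B2 * w) @ B2.T
    raw = 2.0 * wtot - s[:, None] - s[None, :] + 2.0 * M
    K = raw / (2.0 * wtot)
    K = 0.5 * (K + K.T)
    return KernelMatrix(values=K, gene=gene, weighted=bool(weighted or weights is not None))


def _full_rank_design(X: np.ndarray) -> np.ndarray:
    """Drop collinear columns (QR with column pivoting), warning when needed."""
    from scipy.linalg import qr

    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return X
    logger.warning("design matrix is rank deficient (%d < %d); dropping collinear columns",
                   rank, X.shape[1])
    _, _, piv = qr(X, mode="economic", pivoting=True)
    return X[:, np.sort(piv[:rank])]


def _design(cov: CovariateTable | np.ndarray | None, n: int) -> np.ndarray:
    if cov is None:
        return np.ones((n, 1))
    X = cov.design_matrix() if isinstance(cov, CovariateTable) else np.asarray(cov, float)
    return _full_rank_design(X)


@dataclass
class QuantitativeKernelNull:
    """Cached null linear-model fit for the quantitative score test."""

    X: np.ndarray
    Xp: np.ndarray        # X (X'X)^{-1}
    resid: np.ndarray     # P0 y
    sigma2: float         # RSS / (n - p)
    n: int
    p: int


def quantitative_kernel_null(
    trait: np.ndarray, cov: CovariateTable | np.ndarray | None
) -> QuantitativeKernelNull:
    y = np.asarray(trait, dtype=float)
    if y.std() == 0:
        raise ParameterError("response is constant; score test undefined")
    X = _design(cov, len(y))
    n, p = X.shape
    XtX = X.T @ X
    Xp = np.linalg.solve(XtX, X.T).T          # n x p
    resid = y - X @ (Xp.T @ y)
    sigma2 = float(resid @ resid) / (n - p)
    return QuantitativeKernelNull(X=X, Xp=Xp, resid=resid, sigma2=sigma2, n=n, p=p)


def _satterthwaite_p(Q: float, e: float, var: float) -> tuple[float, float, float]:
    """(p, kappa, nu) from the two-moment scaled chi-square match."""
    kappa = var / (2.0 * e)
    nu = 2.0 * e * e / var
    return float(chi2.sf(Q / kappa, nu)), float(kappa), float(nu)


def score_test_quantitative(
    trait: np.ndarray,
    cov: CovariateTable | np.ndarray | None,
    K: KernelMatrix,
    null: QuantitativeKernelNull | None = None,
) -> GeneTestResult:
    """Variance-component score test of τ = 0 for a quantitative trait.

    With projection P0 = I − X(X'X)⁻¹X' and null variance estimate
    σ̂² = RSS/(n−p): Q = r'Kr/(2σ̂²), null mean e = tr(P0K)/2, and null
    variance Ĩ_ττ = tr(P0KP0K)/2 − (tr(P0KP0)/2)²/(tr(P0P0)/2), using the
    idempotence of P0 for the cross terms.  p-value from κ·χ²_ν.
    """
    if null is None:
        null = quantitative_kernel_null(trait, cov)
    Kv = K.values
    method = "kernel_wibs" if K.weighted else "kernel_ibs"
    n_used = -1  # caller may not know; pipeline fills n_snps_used
    r = null.resid
    Q = float(r @ (Kv @ r)) / (2.0 * null.sigma2)
    KX = Kv @ null.X                                   # n x p
    A = Kv - null.Xp @ (null.X.T @ Kv)                 # P0 K, n x n
    e = 0.5 * (np.trace(Kv) - float(np.sum(null.Xp * KX)))
    i_tt = 0.5 * float(np.sum(A * A.T))
    i_ts = e                                           # tr(P0 K P0)/2 = tr(P0 K)/2
    i_ss = 0.5 * (null.n - null.p)
    var = i_tt - i_ts * i_ts / i_ss
    if e <= 1e-12 or var <= 1e-12:
        return GeneTestResult(gene=K.gene, method=method, statistic=Q, p_value=1.0,
                              n_snps_used=n_used, flags=("degenerate",))
    p, kappa, nu = _satterthwaite_p(Q, e, var)
    return GeneTestResult(gene=K.gene, method=method, statistic=Q, p_value=p,
                          n_snps_used=n_used, kappa=kappa, nu=nu)


@dataclass
class BinaryKernelNull:
    """Cached null logistic fit and weighted-projection pieces."""

    X: np.ndarray
    mu: np.ndarray
    d: np.ndarray         # mu (1 - mu)
    DX: np.ndarray        # diag(d) X
    Minv_DXt: np.ndarray  # (X'DX)^{-1} (DX)'
    resid: np.ndarray     # y - mu
    flags: tuple[str, ...] = ()


def binary_kernel_null(
    trait: np.ndarray, cov: CovariateTable | np.ndarray | None
) -> BinaryKernelNull:
    y = np.asarray(trait, dtype=float)
    if not np.all(np.isin(y, [0.0, 1.0])):
        raise ParameterError("binary trait must be coded 0/1")
    if y.min() == y.max():
        raise ParameterError("binary trait has a single class; score test undefined")
    X = _design(cov, len(y))
    fit = fit_logistic(X, y)
    flags: tuple[str, ...] = ()
    if not fit.converged or fit.separated:
        fit = fit_logistic(X, y, ridge=1e-4)
        flags = ("penalized_null",)
    d = fit.mu * (1.0 - fit.mu)
    DX = X * d[:, None]
    Minv_DXt = np.linalg.solve(X.T @ DX, DX.T)
    return BinaryKernelNull(X=X, mu=fit.mu, d=d, DX=DX, Minv_DXt=Minv_DXt,
                            resid=y - fit.mu, flags=flags)


def score_test_binary(
    trait: np.ndarray,
    cov: CovariateTable | np.ndarray | None,
    K: KernelMatrix,
    null: BinaryKernelNull | None = None,
) -> GeneTestResult:
    """Variance-component score test of τ = 0 for a binary trait.

    Null logistic fit gives μ̂; Q = (y−μ̂)'K(y−μ̂)/2, and with the working
    variance D = diag(μ̂(1−μ̂)) and P0 = D − DX(X'DX)⁻¹X'D the null moments
    are e = tr(P0K)/2 and Var = tr(P0KP0K)/2; p-value from κ·χ²_ν.
    """
    if null is None:
        null = binary_kernel_null(trait, cov)
    Kv = K.values
    method = "kernel_wibs" if K.weighted else "kernel_ibs"
    r = null.resid
    Q = 0.5 * float(r @ (Kv @ r))
    DK = Kv * null.d[:, None]                       # D K
    A = DK - null.DX @ (null.Minv_DXt @ Kv)         # P0 K, n x n
    e = 0.5 * float(np.trace(A))
    var = 0.5 * float(np.sum(A * A.T))
    if e <= 1e-12 or var <= 1e-12:
        return GeneTestResult(gene=K.gene, method=method, statistic=Q, p_value=1.0,
                              n_snps_used=-1, flags=null.flags + ("degenerate",))
    p, kappa, nu = _satterthwaite_p(Q, e, var)
    return GeneTestResult(gene=K.gene, method=method, statistic=Q, p_value=p,
                          n_snps_used=-1, kappa=kappa, nu=nu, flags=null.flags)


__all__ = [
    "KERNEL_METHODS", "KernelMatrix", "ibs_kernel",
    "QuantitativeKernelNull", "quantitative_kernel_null", "score_test_quantitative",
    "BinaryKernelNull", "binary_kernel_null", "score_test_binary",
]
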