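"""Internal least-squares and logistic-regression helpers.

These are deliberately minimal: the gene-level tests need many thousands of
small regression fits with warm starts and explicit rank/degeneracy handling,
so the fits are done with plain linear algebra rather than a full GLM stack.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and rank of an OLS fit (lstsq, rank-revealing)."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


@dataclass
class LogisticFit:
    beta: np.ndarray
    mu: np.ndarray
    loglik: float
    converged: bool
    separated: bool


def logistic_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + e^eta), computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    beta0: np.ndarray | None = None,
    max_iter: int = 60,
    tol: float = 1e-10,
    ridge: float = 0.0,
) -> LogisticFit:
    """IRLS logistic fit with a tiny Levenberg-style fallback on singular
    weight matrices.  ``ridge`` > 0 gives a weakly penalized fit (used as a
    fallback when the unpenalized likelihood has no maximum)."""
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else beta0.astype(float).copy()
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        XtWX = (X * w[:, None]).T @ X
        if ridge > 0.0:
            XtWX = XtWX + ridge * np.eye(p)
        grad = X.T @ (y - mu) - (ridge * beta if ridge > 0.0 else 0.0)
        try:
            step = np.linalg.solve(XtWX, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(XtWX, grad, rcond=None)[0]
        beta = beta + step
        ll = logistic_loglik(y, np.clip(X @ beta, -30.0, 30.0))
        if ridge > 0.0:
            ll -= 0.5 * ridge * float(beta @ beta)
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1.0):
            converged = True
            ll_old = ll
            break
        ll_old = ll
    eta = np.clip(X @ beta, -30.0, 30.0)
    mu = 1.0 / (1.0 + np.exp(-eta))
    # quasi-separation heuristic: fitted probabilities pinned at 0/1 with a
    # still-growing linear predictor
    separated = bool(np.abs(X @ beta).max() > 25.0)
    return LogisticFit(beta=beta, mu=mu, loglik=logistic_loglik(y, eta),
                       converged=converged, separated=separated)


def rao_score_test(
    X0: np.ndarray, Z: np.ndarray, y: np.ndarray, mu0: np.ndarray
) -> tuple[float, int]:
    """Rao score test of the Z coefficients at the null logistic fit.

    Returns (statistic, df); the statistic is U' V^- U with the efficient
    information V of Z adjusted for X0, using a pseudo-inverse so collinear
    score columns reduce df instead of failing.
    """
    w = mu0 * (1.0 - mu0)
    U = Z.T @ (y - mu0)
    ZtWZ = (Z * w[:, None]).T @ Z
    ZtWX = (Z * w[:, None]).T @ X0
    XtWX = (X0 * w[:, None]).T @ X0
    V = ZtWZ - ZtWX @ np.linalg.lstsq(XtWX, ZtWX.T, rcond=None)[0]
    V = 0.5 * (V + V.T)
    vals, vecs = np.linalg.eigh(V)
    keep = vals > max(vals.max(), 0.0) * 1e-10 if len(vals) else np.zeros(0, bool)
    df = int(keep.sum())
    if df == 0:
        return 0.0, 0
    Uv = vecs[:, keep].T @ U
    stat = float(Uv @ (Uv / vals[keep]))
    return stat, df
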