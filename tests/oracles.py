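"""Independent brute-force oracles used by the tests.

Everything here is written from the definitions with explicit loops and
dense matrix algebra, sharing no code with the package implementation.
"""
from __future__ import annotations

import numpy as np
from scipy.stats import chi2


def ibs_kernel_bruteforce(counts: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Per-SNP loop over pairs: K_ij = sum_l w_l (2 - |c_il - c_jl|) / (2 sum w)."""
    n, s = counts.shape
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            acc = 0.0
            for l in range(s):
                acc += w[l] * (2 - abs(int(counts[i, l]) - int(counts[j, l])))
            K[i, j] = acc / (2.0 * w.sum())
    return K


def quant_score_test_bruteforce(y, X, K):
    """Quantitative variance-component score test from explicit projections."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    P0 = np.eye(n) - X @ np.linalg.inv(X.T @ X) @ X.T
    r = P0 @ y
    sigma2 = (r @ r) / (n - p)
    Q = (r @ K @ r) / (2 * sigma2)
    e = np.trace(P0 @ K) / 2
    i_tt = np.trace(P0 @ K @ P0 @ K) / 2
    i_ts = np.trace(P0 @ K @ P0) / 2
    i_ss = np.trace(P0 @ P0) / 2
    var = i_tt - i_ts**2 / i_ss
    kappa = var / (2 * e)
    nu = 2 * e**2 / var
    p_val = chi2.sf(Q / kappa, nu)
    return Q, e, var, p_val


def logistic_mle_bruteforce(X, y):
    """Newton-Raphson logistic MLE from the score equations."""
    beta = np.zeros(X.shape[1])
    for _ in range(200):
        mu = 1 / (1 + np.exp(-(X @ beta)))
        W = np.diag(mu * (1 - mu))
        step = np.linalg.solve(X.T @ W @ X, X.T @ (y - mu))
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    return beta


def binary_score_test_bruteforce(y, X, K):
    """Binary variance-component score test from explicit matrices."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    beta = logistic_mle_bruteforce(X, y)
    mu = 1 / (1 + np.exp(-(X @ beta)))
    D = np.diag(mu * (1 - mu))
    P0 = D - D @ X @ np.linalg.inv(X.T @ D @ X) @ X.T @ D
    r = y - mu
    Q = (r @ K @ r) / 2
    e = np.trace(P0 @ K) / 2
    var = np.trace(P0 @ K @ P0 @ K) / 2
    kappa = var / (2 * e)
    nu = 2 * e**2 / var
    return Q, e, var, chi2.sf(Q / kappa, nu)


def auc_mann_whitney_bruteforce(p_causal, p_noncausal):
    """AUC as the pairwise probability that a causal test outranks (has a
    smaller p-value than) a noncausal one, ties counting 1/2."""
    wins = 0.0
    for a in p_causal:
        for b in p_noncausal:
            if a < b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(p_causal) * len(p_noncausal))


def twins_bruteforce(counts, snp_ids, causal_ids):
    """All-pairs column-equality scan for genotype collisions."""
    causal_set = set(causal_ids)
    idx = {s: j for j, s in enumerate(snp_ids)}
    pairs = []
    for j, snp in enumerate(snp_ids):
        if snp in causal_set:
            continue
        for c in causal_ids:
            if np.array_equal(counts[:, j], counts[:, idx[c]]):
                pairs.append((str(snp), str(c)))
    return sorted(set(pairs))
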