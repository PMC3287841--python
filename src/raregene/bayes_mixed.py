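"""Bayesian mixed-effects model pooling phenotype replicates.

The model treats each individual's total genetic effect g_i as a random
effect shared across all R phenotype replicates and the environmental effect
as a fixed effect:

    quantitative:  y_ik = g_i + x_i' beta_E + e_ik,   e_ik ~ N(0, sigma^2)
    binary:        logit P(y_ik = 1) = g_i + x_i' beta_E

with priors g_i ~ N(0, sigma_g^2), beta_E ~ N(0, Sigma_beta) (diagonal), and
noninformative inverse-gamma hyperpriors on sigma_g^2, sigma^2 and the
diagonal of Sigma_beta.  The linear model is fitted by a blocked Gibbs
sampler with exact conjugate full conditionals; the logistic model uses
Polya-Gamma data augmentation, which restores normal/inverse-gamma
conditionals.

Two downstream uses: (a) decomposing phenotypic variance into genetic,
environmental and residual parts; (b) the posterior-mean genetic effects
g_i serve as a replicate-pooled quantitative response for gene-level tests.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, UndefinedStatisticError


@dataclass
class Priors:
    """Inverse-gamma hyperparameters (shape, scale) for the three variance
    blocks.  The defaults are the conventional noninformative IG(1e-3, 1e-3)."""

    a_sigma: float = 1e-3
    b_sigma: float = 1e-3
    a_g: float = 1e-3
    b_g: float = 1e-3
    a_beta: float = 1e-3
    b_beta: float = 1e-3

    def validate(self) -> None:
        for v in (self.a_sigma, self.b_sigma, self.a_g, self.b_g, self.a_beta, self.b_beta):
            if v <= 0:
                raise ParameterError("prior shapes and scales must be > 0")


@dataclass
class MCMCSettings:
    iterations: int = 10_000
    burn_in: int = 2_000
    thin: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.iterations <= self.burn_in:
            raise ParameterError("iterations must exceed burn_in")
        if self.thin < 1:
            raise ParameterError("thin must be >= 1")


@dataclass
class MixedModelSpec:
    """Responses (n × R), environmental design matrix (n × p, intercept
    included), priors and chain settings."""

    responses: np.ndarray
    design: np.ndarray
    priors: Priors = field(default_factory=Priors)
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)

    def __post_init__(self) -> None:
        self.responses = np.atleast_2d(np.asarray(self.responses, dtype=float))
        self.design = np.asarray(self.design, dtype=float)
        if self.responses.shape[0] != self.design.shape[0]:
            raise ParameterError("responses and design disagree on n")
        if np.linalg.matrix_rank(self.design) < self.design.shape[1]:
            raise ParameterError("design matrix must be full column rank")
        self.priors.validate()
        self.mcmc.validate()


@dataclass
class PosteriorSummary:
    g_mean: np.ndarray
    g_sd: np.ndarray
    beta_mean: np.ndarray
    sigma_g2_mean: float
    sigma2_mean: float | None
    ci: dict[str, tuple[float, float]]
    draws: dict[str, np.ndarray]
    diagnostics: dict[str, float]
    flags: tuple[str, ...] = ()

    @property
    def n_individuals(self) -> int:
        return len(self.g_mean)


@dataclass
class VarianceDecomposition:
    prop_genetic: float
    prop_environmental: float
    prop_residual: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.prop_genetic, self.prop_environmental, self.prop_residual)


# ---------------------------------------------------------------------------
# conjugate full-conditional moments (exposed for direct verification)

def g_conditional_moments(
    resid_sums: np.ndarray, R: int, sigma2: float, sigma_g2: float
) -> tuple[np.ndarray, float]:
    """Mean vector and (common) variance of g_i | rest.

    ``resid_sums[i] = sum_k (y_ik - x_i' beta)``: pooling the individual's R
    residuals, precision = R/sigma^2 + 1/sigma_g^2.
    """
    prec = R / sigma2 + 1.0 / sigma_g2
    return (resid_sums / sigma2) / prec, 1.0 / prec


def beta_conditional_moments(
    X: np.ndarray, y_minus_g_sums: np.ndarray, R: int, sigma2: float,
    sigma_beta: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and covariance of beta_E | rest.

    ``y_minus_g_sums[i] = sum_k (y_ik - g_i)``; precision
    = R X'X / sigma^2 + diag(1/sigma_beta).
    """
    prec = R * (X.T @ X) / sigma2 + np.diag(1.0 / sigma_beta)
    cov = np.linalg.inv(prec)
    mean = cov @ (X.T @ y_minus_g_sums) / sigma2
    return mean, cov


def ig_conditional_params(a0: float, b0: float, count: float, ssq: float) -> tuple[float, float]:
    """Posterior (shape, scale) of an inverse-gamma variance given ``count``
    Gaussian observations with summed squares ``ssq``."""
    return a0 + 0.5 * count, b0 + 0.5 * ssq


def _draw_inverse_gamma(rng: np.random.Generator, shape: float, scale: float, size=None):
    return scale / rng.gamma(shape, 1.0, size=size)


# ---------------------------------------------------------------------------
# linear-model Gibbs sampler

@dataclass
class _State:
    g: np.ndarray
    beta: np.ndarray
    sigma2: float
    sigma_g2: float
    sigma_beta: np.ndarray  # diagonal of Sigma_beta


def gibbs_sweep_linear(
    state: _State, Y: np.ndarray, X: np.ndarray, priors: Priors,
    rng: np.random.Generator,
) -> _State:
    """One full scan of the blocked Gibbs sampler for the linear model."""
    n, R = Y.shape
    p = X.shape[1]
    xb = X @ state.beta
    # g | rest
    resid_sums = Y.sum(axis=1) - R * xb
    g_mean, g_var = g_conditional_moments(resid_sums, R, state.sigma2, state.sigma_g2)
    g = g_mean + np.sqrt(g_var) * rng.standard_normal(n)
    # beta | rest
    yg_sums = Y.sum(axis=1) - R * g
    b_mean, b_cov = beta_conditional_moments(X, yg_sums, R, state.sigma2, state.sigma_beta)
    L = np.linalg.cholesky(b_cov + 1e-12 * np.eye(p))
    beta = b_mean + L @ rng.standard_normal(p)
    # sigma^2 | rest
    E = Y - g[:, None] - (X @ beta)[:, None]
    a, b = ig_conditional_params(priors.a_sigma, priors.b_sigma, n * R, float((E * E).sum()))
    sigma2 = float(_draw_inverse_gamma(rng, a, b))
    # sigma_g^2 | rest
    a, b = ig_conditional_params(priors.a_g, priors.b_g, n, float(g @ g))
    sigma_g2 = float(_draw_inverse_gamma(rng, a, b))
    # Sigma_beta diagonal | rest
    a = priors.a_beta + 0.5
    bvec = priors.b_beta + 0.5 * beta**2
    sigma_beta = _draw_inverse_gamma(rng, a, bvec)
    return _State(g=g, beta=beta, sigma2=sigma2, sigma_g2=sigma_g2, sigma_beta=sigma_beta)


def _ess_rhat(x: np.ndarray) -> tuple[float, float]:
    """Effective sample size and split-chain R-hat of a 1-d draw sequence."""
    import arviz as az

    m = len(x) // 2
    arr = np.stack([x[:m], x[m:2 * m]])
    return float(az.ess(arr)), float(az.rhat(arr))


def _summarize(
    draws: dict[str, np.ndarray], g_draws: np.ndarray, beta_draws: np.ndarray,
    flags: tuple[str, ...],
) -> PosteriorSummary:
    ci = {k: (float(np.quantile(v, 0.025)), float(np.quantile(v, 0.975)))
          for k, v in draws.items() if v.ndim == 1}
    diagnostics: dict[str, float] = {}
    for k, v in draws.items():
        if v.ndim == 1 and len(v) >= 8:
            ess, rhat = _ess_rhat(v)
            diagnostics[f"ess_{k}"] = ess
            diagnostics[f"rhat_{k}"] = rhat
    return PosteriorSummary(
        g_mean=g_draws.mean(axis=0),
        g_sd=g_draws.std(axis=0),
        beta_mean=beta_draws.mean(axis=0),
        sigma_g2_mean=float(draws["sigma_g2"].mean()),
        sigma2_mean=float(draws["sigma2"].mean()) if "sigma2" in draws else None,
        ci=ci,
        draws=draws,
        diagnostics=diagnostics,
        flags=flags,
    )


def gibbs_linear(spec: MixedModelSpec) -> PosteriorSummary:
    """Blocked Gibbs sampler for the replicated linear mixed model."""
    Y, X = spec.responses, spec.design
    n, R = Y.shape
    p = X.shape[1]
    rng = np.random.default_rng(spec.mcmc.seed)
    beta0 = np.linalg.lstsq(X, Y.mean(axis=1), rcond=None)[0]
    resid0 = Y - (X @ beta0)[:, None]
    state = _State(
        g=np.zeros(n), beta=beta0,
        sigma2=max(float(resid0.var()), 1e-6),
        sigma_g2=max(float(resid0.mean(axis=1).var()), 1e-6),
        sigma_beta=np.ones(p),
    )
    kept_g, kept_beta, kept_s2, kept_sg2 = [], [], [], []
    for it in range(spec.mcmc.iterations):
        state = gibbs_sweep_linear(state, Y, X, spec.priors, rng)
        if it >= spec.mcmc.burn_in and (it - spec.mcmc.burn_in) % spec.mcmc.thin == 0:
            kept_g.append(state.g)
            kept_beta.append(state.beta)
            kept_s2.append(state.sigma2)
            kept_sg2.append(state.sigma_g2)
    g_draws = np.array(kept_g)
    beta_draws = np.array(kept_beta)
    draws = {
        "sigma2": np.array(kept_s2),
        "sigma_g2": np.array(kept_sg2),
        "beta": beta_draws,
        "g": g_draws,
    }
    flags: tuple[str, ...] = ()
    if R == 1:
        flags = ("single_replicate",)
    return _summarize(draws, g_draws, beta_draws, flags)


# ---------------------------------------------------------------------------
# logistic model via Polya-Gamma augmentation

_PG_TERMS = 64


def sample_polya_gamma(z: np.ndarray, rng: np.random.Generator,
                       n_terms: int = _PG_TERMS) -> np.ndarray:
    """Draw PG(1, z) via the truncated infinite-sum-of-gammas representation
    with a deterministic tail-mean correction.

    PG(1, z) = (1/2π²) Σ_k  g_k / ((k−1/2)² + z²/(4π²)),  g_k ~ Exp(1).
    The first ``n_terms`` terms are sampled; the remainder is added as its
    expected value via the midpoint-integral approximation
    Σ_{k>K} 1/((k−1/2)² + c²) ≈ arctan(c/K)/c.
    """
    z = np.asarray(z, dtype=float)
    c2 = (z / (2.0 * np.pi)) ** 2
    k = np.arange(1, n_terms + 1) - 0.5
    denom = k[:, None] ** 2 + c2.ravel()[None, :]
    gam = rng.standard_exponential(size=denom.shape)
    s = (gam / denom).sum(axis=0)
    c = np.sqrt(c2.ravel())
    tail = np.where(c < 1e-8, 1.0 / n_terms, np.arctan(c / n_terms) / np.where(c < 1e-8, 1.0, c))
    return ((s + tail) / (2.0 * np.pi**2)).reshape(z.shape)


def mcmc_logistic(spec: MixedModelSpec) -> PosteriorSummary:
    """Polya-Gamma-augmented Gibbs sampler for the replicated logistic model."""
    Y, X = spec.responses, spec.design
    if not np.all(np.isin(Y, [0.0, 1.0])):
        raise ParameterError("logistic model needs 0/1 responses")
    n, R = Y.shape
    p = X.shape[1]
    flags: tuple[str, ...] = ()
    if Y.min() == Y.max():
        flags = ("degenerate_constant_response",)
    rng = np.random.default_rng(spec.mcmc.seed)
    kappa_sums = (Y - 0.5).sum(axis=1)
    state = _State(g=np.zeros(n), beta=np.zeros(p), sigma2=1.0, sigma_g2=1.0,
                   sigma_beta=np.ones(p))
    kept_g, kept_beta, kept_sg2 = [], [], []
    for it in range(spec.mcmc.iterations):
        psi = state.g[:, None] + (X @ state.beta)[:, None]  # n x R (same per k)
        omega = sample_polya_gamma(np.broadcast_to(psi, (n, R)), rng)
        om_sums = omega.sum(axis=1)
        # g | rest
        prec_g = om_sums + 1.0 / state.sigma_g2
        mean_g = (kappa_sums - om_sums * (X @ state.beta)) / prec_g
        state.g = mean_g + rng.standard_normal(n) / np.sqrt(prec_g)
        # beta | rest
        prec_b = (X * om_sums[:, None]).T @ X + np.diag(1.0 / state.sigma_beta)
        bvec = X.T @ (kappa_sums - om_sums * state.g)
        cov = np.linalg.inv(prec_b)
        L = np.linalg.cholesky(0.5 * (cov + cov.T) + 1e-12 * np.eye(p))
        state.beta = cov @ bvec + L @ rng.standard_normal(p)
        # variances
        a, b = ig_conditional_params(spec.priors.a_g, spec.priors.b_g, n, float(state.g @ state.g))
        state.sigma_g2 = float(_draw_inverse_gamma(rng, a, b))
        abeta = spec.priors.a_beta + 0.5
        bbeta = spec.priors.b_beta + 0.5 * state.beta**2
        state.sigma_beta = _draw_inverse_gamma(rng, abeta, bbeta)
        if it >= spec.mcmc.burn_in and (it - spec.mcmc.burn_in) % spec.mcmc.thin == 0:
            kept_g.append(state.g.copy())
            kept_beta.append(state.beta.copy())
            kept_sg2.append(state.sigma_g2)
    g_draws = np.array(kept_g)
    beta_draws = np.array(kept_beta)
    draws = {"sigma_g2": np.array(kept_sg2), "beta": beta_draws, "g": g_draws}
    return _summarize(draws, g_draws, beta_draws, flags)


# ---------------------------------------------------------------------------
# downstream summaries

def variance_decomposition(
    post: PosteriorSummary, design: np.ndarray
) -> VarianceDecomposition:
    """Partition phenotypic variance using posterior means.

    V_g = E[sigma_g^2 | data]; V_E = empirical variance over individuals of
    X @ E[beta_E | data] (the intercept column is constant and contributes
    nothing); V_res = E[sigma^2 | data] (0 for the logistic model).
    """
    X = np.asarray(design, dtype=float)
    v_g = post.sigma_g2_mean
    v_e = float((X @ post.beta_mean).var())
    v_res = post.sigma2_mean if post.sigma2_mean is not None else 0.0
    total = v_g + v_e + v_res
    if total <= 0:
        raise UndefinedStatisticError("all variance components are zero")
    return VarianceDecomposition(v_g / total, v_e / total, v_res / total)


def genetic_effect_response(post: PosteriorSummary) -> np.ndarray:
    """Posterior-mean genetic effects g_i, for use as a quantitative response
    in gene-level tests (covariate effects already absorbed; downstream tests
    fit an intercept-only null)."""
    return post.g_mean.copy()


__all__ = [
    "Priors", "MCMCSettings", "MixedModelSpec", "PosteriorSummary",
    "VarianceDecomposition", "g_conditional_moments", "beta_conditional_moments",
    "ig_conditional_params", "gibbs_sweep_linear", "gibbs_linear",
    "sample_polya_gamma", "mcmc_logistic", "variance_decomposition",
    "genetic_effect_response",
]
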