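# Methods

`raregene` implements gene-level association testing for rare variants in a
cohort of unrelated individuals, a Bayesian mixed-effects model that pools
phenotype replicates, an evaluation layer, and a synthetic mini-exome
generator that provides the study conditions for all of it.

## Statistical model

For individual *i* with covariate vector *X_i* (Age, Sex, Smoke, and
reference-coded Population indicators) and minor-allele count vector *G_ik*
over the SNPs of gene *k*, the trait is modeled as

- quantitative: `y_i = alpha' X_i + h(G_ik) + e_i`
- binary: `logit P(y_i = 1) = alpha' X_i + h(G_ik)`

and every gene-level test is a test of `h = 0`, adjusting for covariates.
The package provides two families for `h`.

### Collapsing / burden tests

`h(G_ik) = beta * g_ik` for a scalar (or two-column) per-individual score:

- **collapse** — indicator that the individual carries ≥ 1 minor allele at
  any *rare* SNP of the gene (rare means MAF < 0.05, strictly);
- **proportion** — fraction of the gene's rare SNPs at which the individual
  carries ≥ 1 minor allele (carrier presence, not dosage; a dosage variant is
  available via `dosage=True`);
- **wsum** — `sum_l w_l c_il` over *all* SNPs of the gene with
  `w_l = 1 / sqrt(n q~_l (1 - q~_l))`, where
  `q~_l = (2 n q_l + 1) / (2 n + 2)` is an add-one allele pseudo-count
  estimate of the MAF computed from the full sample.  The weights downweight
  common SNPs smoothly, so no hard MAF filter is applied.  The pseudo-count
  keeps monomorphic columns (which real exome matrices contain and the
  generator deliberately retains) at a finite weight.
- **cmc** — two weighted-sum scores computed separately over the
  nonsynonymous SNPs and over the synonymous-plus-unknown SNPs of the gene,
  tested jointly (ambiguous annotations are pooled with synonymous).  With
  shared weights the two columns add up exactly to the all-SNP weighted sum.

The test is a likelihood-ratio test of all score coefficients being zero —
ordinary least squares for quantitative traits, an IRLS logistic fit with a
warm start from the cached null fit for binary traits.  A likelihood-ratio
rather than Wald test was chosen because it behaves better for
near-degenerate scores.  Score columns with zero variance are dropped (the
degrees of freedom shrink accordingly); a score collinear with the
covariates contributes no rank and yields a flagged degenerate result with
p = 1 rather than an error.  When the logistic alternative separates, the
test falls back to a Rao score test evaluated at the null fit, flagged
`score_fallback`; when the *null* fit separates, a weakly ridge-penalized
null is used and flagged.

### IBS-kernel variance-component score tests

The gene effect is treated nonparametrically, `h ~ N(0, tau K)`, with the
genetic-similarity kernel built from identity-by-state allele sharing:

    K_ij = sum_l w_l * (2 - |c_il - c_jl|) / (2 sum_l w_l).

The normalization by the maximal attainable weighted similarity keeps
`K_ij` in [0, 1] with unit diagonal; it bounds the scale of the score
statistic and stabilizes the moment matching (whether the original kernel
was normalized is a dialect choice; it cancels from the test's asymptotics
and is documented here as this package's convention).  The kernel weights
default to the same stabilized inverse-variance weights as the burden tests
so that "similarity in rarer alleles counts more"; `weighted=False` gives
the unweighted IBS kernel (all `w_l = 1`).  Per-SNP IBS terms are PSD, so K
is PSD by construction.

Testing `h = 0` reduces to the variance component `tau = 0`, tested with a
quadratic-form score statistic on null-model residuals:

- quantitative: fit `y ~ X` by OLS, let `P0 = I - X (X'X)^-1 X'`,
  `sigma^2_hat = RSS / (n - p)` (the unbiased denominator), and
  `Q = r' K r / (2 sigma^2_hat)` with `r = P0 y`.  Null mean
  `e = tr(P0 K)/2` and variance
  `I~ = tr(P0 K P0 K)/2 - (tr(P0 K P0)/2)^2 / (tr(P0 P0)/2)`
  (the efficient information, profiling out sigma^2; idempotence of `P0`
  collapses the cross term to `e`).
- binary: fit the null logistic model, `D = diag(mu(1-mu))`,
  `P0 = D - D X (X'D X)^-1 X' D`, `Q = (y-mu)' K (y-mu) / 2`, null mean
  `tr(P0 K)/2`, variance `tr(P0 K P0 K)/2`.

The p-value comes from the two-moment Satterthwaite match `kappa chi^2_nu`
with `kappa = Var/(2e)`, `nu = 2e^2/Var` — the classical score-test
approximation for variance components.  An exact mixture-of-chi-squares
(Davies/Liu) evaluation is deliberately out of scope.  Explicit estimation
of `h` itself (the penalized-likelihood / representer solution with tuning
parameter lambda and coefficients alpha) is not implemented: hypothesis
testing needs only the null fit, so lambda and alpha have no data structure
in this package.

Both tests reuse one null fit across all genes and, for quantitative
traits, compute the trace-based null moments once per gene across all
phenotype replicates (they depend only on the design matrix).  All trace
computations use the low-rank structure of `P0`, so a gene costs
`O(n^2 (p + c))` rather than `O(n^3)`.

### Bayesian mixed-effects model across replicates

With R phenotype replicates on fixed genotypes, the per-individual total
genetic effect is a random effect shared across replicates:

    y_ik = g_i + x_i' beta_E + e_ik,  e_ik ~ N(0, sigma^2)   (quantitative)
    logit P(y_ik = 1) = g_i + x_i' beta_E                     (binary)

with `g_i ~ N(0, sigma_g^2)`, `beta_E ~ N(0, Sigma_beta)` (diagonal), and
inverse-gamma hyperpriors on all variances, IG(0.001, 0.001) by default.
That default is the conventional "noninformative" choice; it is nearly
improper, so posteriors for very small variance components can be sensitive
to it — the shapes/scales are exposed in `Priors` and proper values (e.g.
IG(3, 3)) are used wherever prior moments must exist.

The linear model is sampled by a blocked Gibbs sampler with exact conjugate
full conditionals (independent normals for g pooling each individual's R
residuals; a multivariate normal for beta_E; inverse gammas for the
variances).  The logistic model uses Polya-Gamma data augmentation, which
restores the same conjugate structure with no tuning.  PG(1, z) variables
are drawn from the infinite-sum-of-gammas representation truncated at 64
terms with the remainder added as its expected value (a midpoint-integral
closed form); this vectorizes over all n×R auxiliary variables.  The
truncation leaves the mean exact and the variance very slightly low; the
linear-model sampler — the one used for the variance decompositions — is
exact, and is validated by a Geweke-style joint-distribution test
(marginal-conditional versus successive-conditional simulators) in the test
suite.  Default chain: 10,000 iterations, 2,000 burn-in, thinning 5, one
chain; effective sample size and split-chain R-hat are always reported in
the posterior diagnostics.

The variance decomposition uses posterior means: `V_g = E[sigma_g^2]`,
`V_E = var_i(X E[beta_E])` (plug-in at the posterior-mean coefficients;
the intercept column is constant and contributes nothing), and
`V_res = E[sigma^2]`; the three are normalized to proportions.  Treating
the genetic share as posterior-mean `sigma_g^2` rather than the empirical
variance of the posterior-mean `g` is a convention; the two differ by
shrinkage and agree as R grows.  The posterior-mean `g_i` is also exposed
as a replicate-pooled, covariate-free quantitative response for the
gene-level tests (their null is then intercept-only); in the conjugate
model it shrinks each individual's mean residual by
`R sigma_g^2 / (R sigma_g^2 + sigma^2)`.

## The synthetic mini-exome generator

The generator reproduces the observable structure of a mini-exome
association study of ~697 unrelated individuals; the exact trait-generating
equations of such benchmark datasets are typically not public, so it targets
structure, not any specific dataset's values:

- **Site-frequency spectrum.**  Per-SNP MAF comes from a two-component
  mixture: with probability 0.872 (= the emulated exome's rare fraction)
  `q = 0.05 Beta(0.3, 2.5)`, else `q = 0.05 + 0.45 Beta(0.8, 2.5)`.  The
  rare component is calibrated so ~39% of rare SNPs fall below the
  expected-singleton frequency `1/(2*697)`, matching the singleton-heavy
  spectrum of exome data.  Genotypes are Binomial(2, q) per individual
  (Hardy–Weinberg), stored MAF is the realized frequency (columns are
  flipped if the sampled allele ends up major), and monomorphic columns are
  retained.
- **Genes.**  SNPs are packed into genes with sizes 1 + negative-binomial
  (mean 7.6 SNPs/gene, heavily right-skewed), giving a realistic mix of
  single-SNP genes and >30-SNP genes.
- **No LD.**  SNPs are independent by default; the *only* mechanism for
  perfectly correlated SNPs is explicit twin injection (below).  This is a
  deliberate reduction: the confounding phenomenon under study is identical
  genotype distributions, which twins reproduce directly.
- **Causal architectures.**  Causal SNPs are nonsynonymous, polymorphic and
  rare (MAF < 0.05) by default; `maf_linked` effects follow
  `|beta| = c |log10 q|` (rarer → larger), `maf_independent` effects are
  exponential magnitudes independent of MAF.  Effects are rescaled so the
  genetic component's population variance equals the trait architecture's
  genetic fraction; environmental coefficients are scaled the same way, and
  residual noise makes total variance ~1.  Default architectures
  (genetic, environmental, residual): Q1 (0.206, 0.161, 0.633) — both
  sources; Q2 (0.124, 0.008, 0.868) — almost purely genetic;
  Q4 (0, 0.787, 0.213) — no genetic contribution.  Disease status is drawn
  from a logistic model whose intercept is solved by root-finding for a
  target prevalence (default 0.30).
- **Replicates.**  Genetic and environmental components are fixed; only the
  residual (and the Bernoulli draw) is re-sampled per replicate, each from
  an independently spawned seed stream.
- **Twin injection.**  `inject_twins` overwrites randomly chosen noncausal
  SNP columns (preferentially in genes without causal SNPs) with exact
  copies of causal columns and records the pairs.  This reproduces the
  mechanism by which a noncausal — possibly synonymous — SNP becomes
  statistically indistinguishable from a causal one.

For the method-comparison scenarios the causal genes are drawn from genes
with ≥ 6 eligible SNPs and each eligible SNP becomes causal with
probability 0.4: causal genes in exome simulations are typically sizeable
genes in which only a minority of sites is functional, and that sparse
within-gene architecture is what differentiates the methods.

**What the generator does not emulate** — linkage disequilibrium (beyond
exact twins), population-stratified allele frequencies, relatedness,
genotype missingness and sequencing error, and gene length correlated with
causality.  Passing tests therefore demonstrate the methods' behavior under
clean Hardy–Weinberg, LD-free conditions; on real exome data, LD produces
many *near*-collisions (the `near_collisions` report covers these) and
stratification can confound both burden and kernel tests beyond what the
Population indicator absorbs.

## Numerical choices and degenerate inputs

- Rare threshold: MAF < 0.05, strictly.  "Minor" allele is decided per
  column from the sample; exact 0.5 columns keep their sampled orientation.
- Burden LRT uses `n log(RSS0/RSS1) ~ chi^2` (quantitative); at the n ≥ 500
  used throughout, the difference from the F-test is negligible.
- Kernel degeneracies (zero kernel, zero null variance) return p = 1 with a
  `degenerate` flag rather than NaN; rank-deficient designs drop collinear
  columns with a warning.
- Gibbs samplers are seed-deterministic; the beta draw adds 1e-12 jitter to
  the Cholesky for safety.
- Genes a method cannot score (e.g. no rare SNP for the proportion score)
  are skipped with a logged reason and recorded in the pipeline's
  `skipped_*.tsv`, so method comparisons can account for differential gene
  coverage.
- ROC curves pool gene-replicate pairs (a gene tested in R replicates
  contributes R points); thresholds are the distinct p-values, and the
  trapezoid AUC equals the tie-corrected Mann–Whitney probability.  A gene
  is labeled causal for a trait iff it contains ≥ 1 causal SNP for that
  trait; twin-carrying noncausal genes stay noncausal — that is the
  false-positive story being measured.  Per-replicate curve averaging is
  available as an option but not the default.
- Collisions are exact column equality (byte-hash bucketing verified by
  elementwise comparison, so identical to the brute-force scan);
  near-collisions (correlation above a cutoff) are a separate report.

## Problem sizes used by the test suite and acceptance script

Calibration uses ~2,000 null genes at n = 500 per trait type; the
method-comparison scenarios use n = 697, ~200 genes, R = 20, over 10 seeds;
Gibbs recovery uses n = 200, R = 50 over 5 seeds; the acceptance script
runs a 697 × 3,000-SNP study with R = 20 and reduced chains (4,000
iterations).  These sizes give stable Monte-Carlo estimates for every
check while keeping a full run on one CPU in minutes; they are the
package's reference configuration, not a constraint of the methods.

## Known limitations

- The weight function adopted for the weighted sum and the weighted kernel
  is the inverse-binomial-SD form described above; other published variants
  (e.g. control-only frequency estimates, beta-density weights) are not
  implemented.
- The Satterthwaite tail is approximate; for alpha far below 1e-3 the
  kernel tests' p-values become conservative/anticonservative in the usual
  ways of two-moment matches.
- The logistic sampler's PG truncation is an approximation (exact mean,
  slightly reduced variance); parameter-recovery tests bound its practical
  effect, but the linear sampler is the one with an exactness guarantee.
- `run_gene_tests` materializes one n × n kernel per gene; at n in the
  thousands, memory and the O(n^2) traces dominate.
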