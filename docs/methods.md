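# Methods

## Model

Gene expression across `p` genes is modelled as a Gaussian graphical
model (GGM): observations are multivariate normal, and an edge between
genes `i` and `j` exists iff their partial correlation
`rho_ij` — the correlation after conditioning on all remaining genes —
is nonzero. Because expression studies typically have many more genes
than samples, the empirical covariance is singular and partial
correlations are instead estimated by node-wise regularised regression:
each gene's expression vector `y` is regressed on the matrix `X` of all
other genes,

    y | beta, sigma^2        ~ N(X beta, sigma^2 I)
    beta_w | zeta_w^2        ~ N(0, zeta_w^2)
    zeta_w^2                 ~ InverseGaussian(alpha, gamma)
    1/sigma^2                ~ Gamma(a0, b0)

The inverse-Gaussian scale mixture (density
`alpha/sqrt(2 pi) * exp(alpha gamma) * x^{-3/2} * exp(-(alpha^2/x + gamma^2 x)/2)`,
mean `alpha/gamma`) produces heavier-than-normal marginal tails with a
spike of mass near zero, i.e. sparse shrinkage. Directed coefficients
are symmetrised into partial correlations as the signed geometric mean
`rho_ij = sign(B_ij) sqrt(B_ij B_ji)` when `B_ij` and `B_ji` agree in
sign, and zero otherwise.

### Differential model selection

For two-condition data, each gene is scored under two models: `K=1`
(one regression over the pooled samples — conserved neighbourhood) and
`K=2` (independent regressions per condition — varying neighbourhood).
Model evidence is approximated by the variational lower bound (ELBO);
the `K=2` evidence is the sum of the two per-condition bounds because
the conditions are independent given the model. A gene is called
*differential* when the Bayes factor
`BF = exp(log_evidence_K2 - log_evidence_K1)` strictly exceeds 2
(ties go to the simpler conserved model). Per-condition networks are
then assembled using condition-specific coefficients for differential
genes and pooled coefficients for conserved genes, and edges are called
per condition by local false discovery rate; edges significant in both
conditions are conserved, edges significant in exactly one are
condition-specific.

### Variational inference

The mean-field factorisation `q(beta) q(1/sigma^2) prod_w q(zeta_w^2)`
is optimised by coordinate ascent. Conjugacy gives `q(beta)`
multivariate normal, `q(1/sigma^2)` gamma, and `q(zeta_w^2)`
generalised inverse Gaussian with index −1 (the inverse-Gaussian prior
is GIG(−1/2); the Gaussian coefficient likelihood shifts the index by
−1/2). GIG moments are computed through exponentially scaled Bessel-K
ratios for numerical stability. A convenient property of the GIG(−1)
posterior is that every `E[log zeta^2]` term in the bound cancels
exactly, so the ELBO needs only `E[zeta^2]`, `E[1/zeta^2]` and the GIG
log-normaliser.

Updates run in the order `q(beta) -> q(zeta^2) -> q(1/sigma^2)` from a
deterministic start (`E[1/zeta_w^2] = gamma/alpha`, `E[1/sigma^2] = 1`),
so fits are exactly reproducible with no seed. Iteration stops when the
relative ELBO change falls below `rel_tol` (default 1e-6) or after
`max_iter` (default 500) sweeps. The bound is validated three ways: it
is non-decreasing across sweeps on every fit; with the scale posteriors
frozen to point masses and the noise precision fixed, the coefficient
update reproduces the closed-form ridge posterior to 1e-8; and on a
one-predictor toy model the converged bound sits below (within 2 nats
of) the exact log evidence computed by independent 2-D quadrature.

### Priors and defaults

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.1 | mixing-density parameter; smaller alpha tightens the prior on coefficient scales (prior mean scale is `alpha/gamma`) |
| `gamma` | 1.0 | mixing-density parameter; larger gamma tightens it |
| `a0, b0` | 1e-3, 1e-3 | vague gamma prior on the noise precision |
| `bf_threshold` | 2 | Bayes factor above which a gene is differential |
| `fdr_cutoff` | 0.025 | local fdr below which an edge is significant |

Data are standardized to zero mean and unit sample standard deviation
before fitting (no intercept). For the `K=2` fits each condition's
submatrix is standardized within itself, so model selection responds to
changes in network structure rather than condition-level location or
scale shifts. The same prior is used at both levels; no additional
sample-size correction is applied beyond what the marginal likelihood
provides.

### Local false discovery rate

Off-diagonal partial correlations are modelled as the two-group mixture
`f(rho) = eta0 f0(rho; kappa) + (1 - eta0) fA(rho)` with null density
`f0 ∝ (1 - rho^2)^{(kappa-3)/2}` on (−1, 1) — the sampling family of an
empirical correlation under independence, with `kappa` an effective
degrees-of-freedom parameter. `kappa` is estimated by matching the
median absolute statistic of the central bulk (values below the 75th
percentile of `|rho|`, presumed mostly null) to the median of the
truncated null, by 1-D root finding on `log kappa`; `eta0` is the ratio
of observed to expected null mass in that region, clamped to [0, 1].
The marginal `f` is a Gaussian kernel density estimate on the Fisher-z
scale mapped back with its Jacobian and symmetrised,
`(f(rho)+f(-rho))/2`. The local fdr `min(1, eta0 f0/f)` is evaluated on
a grid in `|rho|` and post-processed with a running minimum so it is
monotone non-increasing in `|rho|` by construction. When more than half
of the statistics are exactly zero (heavily shrunk sparse fits) the
root-finder has no signal and a wide fallback null is used; zeros are
then never significant, which is the conservative direction. Exact
numerical agreement with any particular external fdr implementation is
not a goal.

## Synthetic ground truth

Networks are simulated by selecting each node pair independently with
probability `edge_fraction` (default 0.04, ≈ 49 expected edges at
p=50, a sparse regime typical of regulatory-network benchmarks),
assigning uniform weights on [−1, 1], and enforcing
positive-definiteness by diagonal dominance (diagonal = 1 + row-wise
absolute sum, then rescaling to unit diagonal). This preserves the
selected zero pattern exactly, but attenuates magnitudes: realized
partial correlations concentrate around 0.1–0.4 and never reach the
raw weights. Observations are i.i.d. multivariate normal draws from
the implied covariance. Differential scenarios copy the condition-1
network and rewire a chosen node subset: incident edges are deleted
and redrawn with probability `edge_fraction` per partner (expected,
not exact, degree preserved) with fresh weights; a null scenario keeps
the two structures identical.

The generator emulates the sparse, weak-signal character of regulatory
networks estimated from expression data, but not microarray
technical noise, non-normality, batch effects, or hub-dominated
(scale-free) topology. Passing benchmarks here therefore demonstrate
the statistical machinery under the model's own assumptions, not
performance on raw microarray data.

## Benchmarks and the independent-analysis baseline

Three designs are scored, always for both the integrated pipeline and
an internal baseline that fits each condition separately and flags
genes whose local-fdr-significant edge sets differ between conditions:

- **Edge recovery (AUC)** — single-condition data; `|rho|` scores
  ranked against the true edge set (the baseline here is partial
  correlation from a Ledoit–Wolf-shrunk covariance inverse).
- **Differential power (MCC)** — 5 of 50 nodes rewired; predicted
  differential genes (BF > 2) against the known changed set.
- **Null calibration (FPR)** — identical structure in both conditions;
  fraction of genes falsely called differential.

The evidence comparison is intrinsically conservative: the `K=2` model
pays a real Occam cost (a second set of coefficient priors and a
second vague noise prior — roughly 12–22 nats at 49 predictors), so
weak structural changes are resolved as conserved and the pooled data
strengthen the shared network estimate. This is why the pipeline's
null false positive rate is near zero while independent per-condition
analysis flags most genes, and why detecting rewired nodes requires
either strong partial correlations (≳ 0.4) or generous sample sizes
(hundreds per condition). The benchmark's relative claims — never
worse than the baseline on power, far better on false positives —
hold at desk scale (10–20 replicates; chosen as the package's default
replicate count).

## Numerical notes and limitations

- Coefficient updates solve an m×m system by Cholesky factorization;
  cost O(m^3) per sweep per gene, fine into the hundreds of genes.
- Degenerate inputs are rejected early with the offending gene named:
  constant columns, non-finite values, conditions with fewer than 3
  samples, duplicate gene names, more than two conditions.
- A Bayes factor exactly equal to the threshold selects the conserved
  model; the comparison is done on the log scale.
- Sign-conflicting directed coefficients yield a zero partial
  correlation per condition independently; mixing pooled and
  per-condition rows for conserved/differential genes can therefore
  produce edges present in one condition's matrix only.
- Only K ∈ {1, 2} conditions are supported; no multiplicity correction
  is applied across genes to the Bayes-factor rule.
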