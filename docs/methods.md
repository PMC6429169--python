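# Methods

## Model

`neurosem` fits a structural equation model that links a panel of candidate
SNPs to a panel of brain-region measurements through a small number of
latent variables, one per *region group* (a set of regions with a shared
transcriptional profile in the healthy brain; the grouping is consumed as
an input table, not derived here). For individual *i* with centred genotype
vector **g**ᵢ ∈ ℝᵖ (additive 0/1/2 coding, centred) and centred, scaled
region vector **x**ᵢ ∈ ℝ^q:

    z_i = A g_i + ε_i,      ε ~ N(0, Ψ),  Ψ = diag(ψ_1..ψ_m)
    x_i = B z_i + ζ_i,      ζ ~ N(0, Θ),  Θ diagonal

This is a MIMIC-type structure: the latents have multiple indicators (the
regions of their group) and multiple causes (the SNPs). Structural
restrictions:

* **B is block sparse** — each latent loads only on its own group's
  regions, so every column of B has a disjoint support.
* **Anchor loadings** — the first region of each group has its loading
  fixed to 1. This identifies the latent scales and orients each latent
  with its anchor region (shrinkage of the anchor ⇒ a lower latent score).
* **Equal region residual variances within a group** — Θ carries one free
  variance per group (the same homoscedasticity assumption PCA makes).
* **Diagonal Ψ** — no free covariances among latent residuals. This is the
  minimal model consistent with the path diagram; correlated latent
  residuals are a known limitation, not an option we expose.
* **Exogenous SNP covariance** — Σ_gg is fixed at the observed SNP
  covariance and never optimised (it is profiled out of the likelihood).

Since the latents are unobserved, fitting matches the observed covariance
S of (g, x) to the model-implied covariance

    Σ(θ) = [ Σ_gg          Σ_gg AᵀBᵀ                    ]
           [ B A Σ_gg      B A Σ_gg AᵀBᵀ + B Ψ Bᵀ + Θ  ]

by minimising the normal-theory discrepancy

    F(θ) = log|Σ| + tr(S Σ⁻¹) − log|S| − (p + q),

which is ≥ 0, vanishes exactly at Σ = S, and whose minimiser is the
Gaussian maximum-likelihood estimate. S uses the ML divisor n throughout.

## Estimation

The free parameters are the q−m non-anchor loadings, the m·p SNP weights,
and the 2m log-variances (log-parameterisation keeps ψ, θ positive). The
optimiser is L-BFGS-B with the analytic gradient
∂F/∂θ_k = tr(Σ⁻¹(Σ−S)Σ⁻¹ · ∂Σ/∂θ_k), alternated with a damped
(Levenberg-style) Fisher-scoring polish that uses the expected information
I_jk = ½ tr(Σ⁻¹ ∂Σ_j Σ⁻¹ ∂Σ_k). The second-order polish matters under a
misspecified grouping, where first-order steps crawl along flat ridges.

Starting values: anchors and free loadings 1, A = 0, ψ = θ = half the mean
observed region variance; up to 5 jittered restarts on failure.
Convergence: projected max-gradient < 1e−6, or relative reduction of F
below 1e−10 (the same termination rule standard SEM fitters apply). The
log-variances are bounded below at log(1e−6): a variance floor that cuts
off Heywood-case ridges (a latent residual variance collapsing to zero
with diverging loadings), which otherwise arise routinely when the fitted
grouping disagrees with the data-generating one. A fit at the floor is a
boundary solution, reported as converged when the projected gradient
criterion holds.

Naive standard errors come from the inverse expected information at the
optimum, (I⁻¹/n)½.

## Robust inference

Genotypes are discrete, so the normal-theory standard errors are replaced
by a sandwich estimate built from empirical fourth moments,

    acov = (ΔᵀWΔ)⁻¹ ΔᵀWΓWΔ (ΔᵀWΔ)⁻¹ / n,

with Δ the Jacobian of the implied-covariance elements, W the normal-theory
weight matrix at the optimum and Γ the empirical covariance of the
sample-covariance elements. Everything is evaluated in the d×d matrix
representation (ΔᵀWΔ = I above; (WΔ)_k = ½Σ⁻¹∂Σ_kΣ⁻¹), so no Kronecker
products or duplication matrices are formed; the Γ contraction reduces to
per-sample quadratic forms. Under exact normality the sandwich collapses to
the naive covariance (verified in a test at n = 5000). Wald p values are
two-sided normal tails of estimate / robust SE. At the default study size
(n = 500, d = 70) Γ is rank deficient (n below the 2485 unique second
moments); this is recorded as a warning on the result and shows up
empirically as mild under-coverage (≈93% for nominal 95% intervals). Only
robust standard errors and Wald p values are provided; a scaled χ² model
test is out of scope.

Latent scores are the conditionally unbiased Bartlett estimator
ẑ = (BᵀΘ⁻¹B)⁻¹BᵀΘ⁻¹x, using the measurement part only (not conditioned on
g, matching the standard estimator).

## Synthetic data

The generator reproduces the study conditions the method was evaluated
under; the defaults *are* those conditions and are not tuned per run:

| parameter | default | meaning |
|---|---|---|
| n_individuals | 500 | cohort size per replicate |
| n_snps | 20 | independent SNPs, MAF ~ Beta(1, 2), HWE genotypes |
| group_sizes | (20,10,10,5,5) | five region groups, q = 50 |
| n_nonzero_a | 10 | SNP→latent weights set to ±1, placed uniformly |
| loading_range | (0.5, 1.5) | uniform latent→region loadings |
| latent_noise_sd / region_noise_sd | 2 / 2 | Gaussian noise on z and x |
| n_phenotype_latents | 2 | latents with phenotype weight ±10 |

The phenotype is Bernoulli(logistic(wᵀz)) with no intercept (none is
stated for the original design; an intercept is available as a config
field). Latents are driven by *centred* genotypes, matching the zero-mean
convention of the model equations. A SNP is a *true effect* if it has a
nonzero weight onto any phenotype-linked latent. Misspecified groupings
are produced by swapping region-group links: each swap exchanges one
region between two groups (preserving group sizes, two misspecified links
per swap) and no region is ever swapped back.

Limits of realism: SNPs carry no linkage disequilibrium, regions are
conditionally independent given their latent, noise is homoscedastic
Gaussian, and the phenotype depends on the latents only. Passing the
simulation study therefore demonstrates correctness of the machinery and
the claimed orderings *under the model's own assumptions*, not performance
on real cohort data.

Reproducibility: a root seed drives per-replicate child seeds through a
counter (`SeedSequence(entropy=root, spawn_key=(k,))`), so any replicate
can be regenerated in isolation.

## Evaluation framework

Per replicate: simulate → centre g, centre+scale x → fit → robust SEs →
Bartlett scores → two comparisons.

**Phenotype prediction (AIC).** Five logistic regressions (with intercept,
AIC = 2(k+1) − 2ℓ): fitted latent scores, the first m principal components
of the scaled regions, all regions, all SNPs + regions, all SNPs. Logistic
fits use IRLS; quasi-perfect prediction of individual samples is tolerated
(as in R's glm), and only complete separation (zero deviance) fails a
replicate.

**SNP retrieval (AUC).** The path from SNP j through latent l carries two
p values: the robust p of A[l, j] and the logistic Wald p of latent l in a
joint regression of the phenotype on all m scores. Combination: *SEM max*
takes max of the pair then min over latents; *SEM Fisher* combines the
pair with −2(ln p₁ + ln p₂) against χ²₄ then takes the min (the two p
values test different hypotheses, so the χ²₄ reference is a heuristic —
documented, not corrected). Baselines: per-SNP ("univariate", GWAS-style)
and joint ("multivariate") logistic p values. Retrieval AUC is the
tie-corrected rank statistic P(score_true < score_false) + ½P(tie),
equivalent to sweeping the score threshold over [0, 1].

Failed replicates (non-convergence, complete separation, a monomorphic
SNP column, or a replicate whose true-effect set is empty) are excluded
from aggregates but counted; a study errs out if more than 20% fail.

## Problem sizes and observed behaviour

The shipped tests run the base condition and sweeps at 10–20 replicates
per cell, the parameter-recovery check at n = 5000 over 10 replicates, and
CI coverage over 200 replicates; `scripts/acceptance.py` recomputes the
same quantities at the sizes recorded in its JSON output. At these sizes
the qualitative results are stable: fitted latents achieve the lowest mean
AIC with the m-PC model close behind; SEM max leads all retrieval
rankings at the base condition; retrieval degrades monotonically with
swapped links. Under heavy region noise the SEM rankings decay toward
chance while SNP-only baselines are unaffected; in this implementation
SEM Fisher falls below the baselines at noise sd 5 and SEM max crosses at
roughly double that, so the crossover point should be read as
implementation-sensitive.

## Numerical choices

* Covariance divisor n (ML convention) everywhere.
* Variance floor 1e−6; weight box ±1e4 (inactive in practice).
* Two-region-group minimum: singleton groups are rejected (loading and
  residual variance not separable), not auto-merged.
* Zero p values are clamped to the smallest positive float before log
  combination, with a warning.
* Degenerate ANOVA cells (zero within-variance, equal means) are flagged
  rather than returned as spurious F values.
* Validation scoring reuses the training fit's B and Θ only; validation
  regions are centred/scaled with their own moments (a documented choice —
  the alternative of freezing training moments is not implemented).
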