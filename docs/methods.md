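# Methods

## Problem and model family

`bvnma` evaluates candidate surrogate endpoints from contrast-level
randomised-trial summaries.  Each two-arm study *i* comparing treatments
*k* (baseline) and *l* (experimental) contributes a pair of effect
estimates: *Y*₁ on the surrogate (e.g. log odds ratio of tumour response)
and *Y*₂ on the final outcome (e.g. log hazard ratio of progression-free
survival), with standard errors σ₁ᵢ, σ₂ᵢ and a within-study correlation
ρ_w that is treated as known input (it usually comes from individual
participant data of one trial and is applied to all rows via a single
override).

The within-study layer is common to all variants:

    (Y₁ᵢ, Y₂ᵢ) ~ N₂( (μ₁ᵢ, μ₂ᵢ), Σᵢ ),   Σᵢ known from (σ₁ᵢ, σ₂ᵢ, ρ_wᵢ).

The variants differ in how the latent true effects μ are modelled:

* **brma** — classical bivariate random-effects meta-analysis: all
  studies exchangeable regardless of contrast, μᵢ ~ N₂(β, T) with one
  common T = [[τ₁², τ₁τ₂ρ], [·, τ₂²]].  ρ is the study-level surrogacy
  correlation pooled over the whole network.
* **1a** — network model with first-order consistency on the means
  (contrast means derive from basic parameters d_j1k vs. the reference,
  so effects "add up around loops") and a free (τ₁, τ₂, ρ) per contrast.
* **1b** — adds *second-order* consistency: the between-study
  covariances themselves must be mutually compatible, enforced by
  writing every contrast effect as a difference of arm-level random
  effects ζ_jk with sd γ_jk and correlation matrix R (2n_t × 2n_t).
  Then τ²_jkl = γ²_jk + γ²_jl − 2ξ_jk,jl γ_jk γ_jl, the cross-covariance
  expands into four ξ-weighted products, and the triangle inequalities
  |τ_jbl − τ_jbk| ≤ τ_jkl ≤ τ_jbl + τ_jbk and the covariance-consistency
  identity hold for every treatment triple by construction.
* **1c** — as 1b, but the arm variances γ² are exchangeable:
  γ²_jk ~ N(0, v_j) truncated to [0, ∞) with v_j ~ Gamma(1.0, 0.01)
  (shape–rate, mean 100), one scale per outcome shared across
  treatments.  The truncated normal sits on the *variance*, as is
  conventional in the BUGS formulation of this hierarchy; the sd is its
  square root.
* **1d** — first-order consistency on the means with one homogeneous T
  for all contrasts (the usual sparse-network simplification).
* **2a–2d** — the same four covariance structures, but the independent
  N(0, 10³) priors on the basic parameters are replaced by an
  exchangeable treatment-level layer: d_j1k = θ_jk − θ_j1 with
  (θ₁k, θ₂k) ~ N₂(0, ½Ω), Ω = [[ω₁², ρ_t ω₁ω₂], [·, ω₂²]].  The ½
  cancels in differences, so cov(d₁kl, d₂kl) = Ω for every contrast; ρ_t
  is the treatment-level surrogacy correlation, and these variants can
  predict final-outcome effects for a treatment that has no
  final-outcome data anywhere in the network.

Priors: β_j ~ N(0, 10⁴); d_j1k ~ N(0, 10³); all heterogeneity and
ancillary sd's uniform on (0, 2) (effects are on log scales, where 2 is
already an enormous between-study sd); every correlation via
(ρ+1)/2 ~ Beta(1.5, 1.5), a symmetric prior on [−1, 1] that vanishes at
±1.  The defaults live in `PriorConfig` and are serialised into every
run manifest.

### Correlation-matrix prior for 1b/2b and 1c/2c

R must be positive semidefinite with unit diagonal.  We parameterise
R = LᵀL with L upper triangular and unit-norm columns given by spherical
angles, one uniform (0, π) prior per angle.  This construction makes the
induced contrast-level priors depend on the treatment ordering; the
ordering is therefore explicit (lexical, reference first, logged in the
manifest) rather than silent.  A sensitivity analysis over orderings is
the user's responsibility; the machinery for it is the `reference` /
`treatments` arguments of `NetworkData`.

### Non-identifiability of θ

The θ_jk enter the likelihood only through differences, so they are
identified only up to a common shift per outcome; the anchoring constant
η is fixed at 0.  Convergence diagnostics are computed on identifiable
quantities (contrast means, τ, ρ, ω, ρ_t) — R-hat on raw θ would flag a
non-problem.

## Inference

Both model layers are Gaussian, so the latent study effects are
integrated out analytically: marginally Yᵢ ~ N₂(mean, Σᵢ + T_kl), and a
study with a missing final-outcome estimate contributes only its
surrogate margin N(mean₁, σ₁ᵢ² + τ₁²_kl).  The resulting 5–32-dimensional
hyperparameter posteriors are sampled with an affine-invariant ensemble
sampler (`emcee`), run as ≥ 2 independent ensembles ("chains") from
jittered data-informed starting points.  Walker draws are pooled within a
chain after warm-up and thinning; split-R̂ across chains gates
convergence (threshold 1.05, breaches are flagged in the manifest and
logged, never silently ignored), and MC error is estimated as
sd/√ESS with an initial-positive-sequence autocorrelation ESS.  All
randomness flows from a single integer seed through `SeedSequence`
derivations, so every fit, cross-validation and simulation replicate is
exactly reproducible and replicates are independently re-runnable.

Default problem sizes: 2 chains, 500 warm-up + 1000 sampling ensemble
steps (thin 2) for interactive fits; the simulation harness uses
400/600 steps for the 5-parameter pooled model and 800/1200 for the
13-parameter contrast-specific model, which give correlation MC errors
comfortably below the 0.02 quality gate used in the reporting.

### Latent effects and DIC

Conditional on a hyperparameter draw, each study's latent effect pair is
Gaussian; we use the degenerate-safe form μ|y ~ N(m + G(y−m), T − GT)
with G = T(T+Σᵢ)⁻¹, which remains correct as T → 0 (for missing-final
rows the conditioning uses the surrogate margin only).  DIC is computed
at the study-effect focus: deviance = −2 × within-study log likelihood at
sampled latent effects, pD = D̄ − D(μ̄), matching the default of
BUGS-family software for this hierarchy.  Because the published DICs for
this model family came from such software and the focus convention is
not printed, small discrepancies against published DIC values are
expected; DIC comparisons within a single run of this package are
internally consistent.

### Prediction and cross-validation

To predict a study's effect on the final outcome, its Y₂ is masked
(missing at random) and the model refitted.  Given each hyperparameter
draw, (Y₁ᵢ, Y₂ᵢ) is bivariate normal with covariance Σᵢ + T_kl, so Y₂ᵢ
is drawn from the exact Gaussian conditional given the observed Y₁ᵢ;
pooling over draws gives the posterior-predictive sample, whose sd
automatically contains both the posterior uncertainty of the latent
effect and the within-study noise σ₂ᵢ.  Take-one-out cross-validation
repeats this for each complete study with an independent fit per target.
Comparison statistics (overlap fraction of the observed CI with the
predicted CrI, absolute error, width ratio, π = p_overlap^(w_pred/w_obs),
and %-reduction vs. a reference model) are computed per study and then
averaged per contrast and overall — never as ratios of averages.  The
observed CI is `estimate ± 1.96·se` since the inputs are summary-level.
Degenerate zero-width observed CIs use a containment indicator and are
flagged.  Note that π is deliberately non-monotone in interval widening:
it rewards overlap and penalises width, and the two effects can trade
off.

Predictions for a new treatment (a contrast with a single study and a
treatment unseen elsewhere) are refused under the consistency-only
variants — the relevant basic parameter would be prior-driven — and
flagged `prior_driven` under the exchangeable variants, where they are
informed by the treatment-level layer.

## Synthetic-data generator

`generate_dataset` draws from the contrast-specific random-effects
process (the free-covariance network model): latent effects from
N₂(d_kl, T_kl), per-outcome within-study sd's uniform on a scenario
range (independently per outcome), observed pairs with correlated
within-study noise.  The four built-in scenarios use a 45-study,
3-treatment loop (15 studies per contrast) and cross pooled vs.
within-contrast surrogacy strength:

| scenario | d (AB, BC, AC) | τ₁ / τ₂ per contrast | ρ (all) | σ range | ρ_w |
|---|---|---|---|---|---|
| 1 | (1,2), (2,1), (3,3) | 0.3/0.6, 0.6/0.3, 0.6/0.6 | 0.9 | 0.15–0.25 | 0.6 |
| 2 | (1,1), (2,2), (3,3) | 0.2/0.3, 0.25/0.25, 0.3/0.2 | 0.9 | 0.05–0.15 | 0.98 |
| 3 | (1,2), (2,1), (3,3) | all 0.4 | 0.25 | 0.15–0.25 | 0.6 |
| 4 | (1,1), (2,2), (3,3) | as scenario 2 | 0.25 | 0.05–0.15 | 0.6 |

All four τ sets satisfy the second-order-consistency triangle
inequalities (checked by `ScenarioSpec.triangle_inequalities_ok`).
Replicate seeds are counter-derived from a master seed so long studies
are resumable and parallelisable.

What the generator does *not* emulate: real networks are unbalanced
(study counts differ wildly per contrast), effect estimates on different
scales can be differentially non-normal, within-study correlations are
estimated with error rather than known, and multi-arm trials induce
correlated contrasts (multi-arm rows are rejected by design).  Passing
simulation checks therefore demonstrates correctness of the machinery
under the model's own assumptions, not robustness to their violation.

## Scale of the shipped studies

The original design of these simulation studies uses 1000 replicates per
cell; the package's test suite and the acceptance script run desk-scale
versions with 20–28 replicates per cell (≥ 50 for the parameter-recovery
check), which keeps each study in the minutes range while leaving the
replicate-mean correlations with a standard error of roughly 0.02–0.03.
Tolerances in the tests account for that extra noise.  Full-scale runs
are a matter of raising `n_reps` (the harness is embarrassingly parallel
across replicates).

## Numerical choices and edge cases

* 2×2 bivariate-normal log densities are evaluated in closed form with
  the determinant floored at 1e-300 purely to avoid -inf/NaN traps at
  inadmissible points (the sampler rejects them via the prior anyway).
* Between-study covariance entries induced by the ancillary structure
  are clipped at 0 from below against rounding; induced correlations are
  clipped to [−1, 1].
* τ₁ = 0 makes the implied surrogacy intercept undefined; those draws
  are reported not-evaluable and excluded from its CrI, with a count.
* The implied intercept for homogeneous-covariance variants combines
  contrast-specific means with the common (ρ, τ), so one intercept per
  contrast is still reported.
* Disconnected networks are rejected at construction; contrasts with
  < 4 studies are flagged by `validate_network` (contrast-level results
  are conventionally not reported for them), and contrasts with < 2
  studies trigger a prior-driven-correlation warning at model build.
* Zero-variance draws cannot occur under the continuous priors; fixed
  between-study covariances (a validation hook) take the degenerate-safe
  conditioning path.

## Known limitations

* Two-arm studies only; arm-level (binomial/survival) likelihoods are
  out of scope — effects must arrive as contrast-level summaries.
* The angular correlation prior is one of several admissible separation
  strategies; its ordering dependence is documented, not removed.
* The ensemble sampler is gradient-free; for much larger networks (many
  tens of treatments) the 2n_t(2n_t−1)/2 angles of models 1b/2b would
  mix slowly and a gradient-based backend would be preferable.  The
  sampler contract (`fit`) is deliberately narrow to allow swapping.
* DIC is reported at a fixed focus; cross-package DIC comparisons are
  only meaningful at the same focus.
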