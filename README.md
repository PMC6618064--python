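# bvnma — bivariate network meta-analysis for surrogate endpoints

`bvnma` is a Python package for evaluating surrogate endpoints from
contrast-level summaries of randomised trials.  A surrogate endpoint
(say, tumour response) is useful when the treatment effect measured on
it predicts the treatment effect on a final clinical outcome (say,
progression-free survival).  Classical bivariate random-effects
meta-analysis (BRMA) pools all studies and estimates one between-study
correlation ρ between the two effects — but in a network of trials
comparing many treatments, the strength of the surrogate relationship
can differ by treatment contrast, and a pooled ρ can be badly
misleading in both directions.

The package implements a family of Bayesian bivariate network
meta-analysis (bvNMA) models that estimate the surrogate relationship
*within* each treatment contrast while borrowing strength across the
network:

| variant | mean structure | between-study covariance |
|---|---|---|
| `brma` | pooled (β₁, β₂) | one common (τ₁, τ₂, ρ) |
| `1a` / `2a` | consistency / exchangeable | free (τ₁, τ₂, ρ) per contrast |
| `1b` / `2b` | consistency / exchangeable | arm-level ancillary effects (second-order consistency) |
| `1c` / `2c` | consistency / exchangeable | as b, exchangeable ancillary variances |
| `1d` / `2d` | consistency / exchangeable | one common (τ₁, τ₂, ρ) |

"Consistency" means contrast means derive from basic parameters vs. a
reference treatment (effects add up around loops); the `2*` variants add
an exchangeable treatment-level layer whose correlation ρ_t measures
*treatment-level* surrogacy and enables predictions for a new treatment.
Second-order consistency (`1b`/`2b`) additionally requires the
between-study covariance matrices of contrasts sharing a treatment to be
mutually compatible (triangle inequalities and a covariance identity),
which is enforced constructively through arm-level random effects.

On top of the models the package provides: surrogacy criteria (per-
contrast ρ with credible intervals and the implied intercept
λ₀ = d₂ − d₁ρτ₂/τ₁), take-one-out cross-validated prediction of the
final-outcome effect from the surrogate effect with the comparison
statistics p_overlap, |m_obs − m_pred|, w_pred/w_obs,
π = p_overlap^(w_pred/w_obs) and %-width-reduction, DIC for model
comparison, and a simulation harness with four built-in data-generating
scenarios.  See `docs/methods.md` for the full model account.

## Worked example

Simulate a 45-study, three-treatment network in which every contrast has
a strong surrogate relationship (ρ = 0.9) but the contrast means are
discordant, then compare the pooled model with the contrast-specific
network model:

```python
import bvnma

spec = bvnma.builtin_scenarios()["1"]      # d_AB=(1,2), d_BC=(2,1), d_AC=(3,3), rho=0.9
data = bvnma.generate_dataset(spec, seed=42)

cfg = bvnma.McmcConfig(n_chains=2, n_warmup=800, n_draws=1200, thin=4, seed=1)
pooled = bvnma.fit(bvnma.build_model(data, "brma"), cfg)
network = bvnma.fit(bvnma.build_model(data, "1a"), cfg)

print(bvnma.summarize(pooled, ["rho"]).round(3)[["mean", "q2_5", "q97_5"]])
print(bvnma.surrogacy_report(network).correlations.round(2))
```

```
       mean   q2_5  q97_5
name
rho   0.548  0.315  0.738

      level name  mean  q2_5  q97_5  near_extreme
0  contrast   AB  0.92  0.69   1.00         False
1  contrast   AC  0.72  0.34   0.93         False
2  contrast   BC  0.63  0.11   0.94         False
```

The pooled between-study correlation (0.55) substantially understates
the surrogacy within each contrast (here generated at 0.9): pooling
mixes the discordant contrast means into the correlation.  The network
model recovers high within-contrast correlations, at the price of wider
intervals per contrast.  The practical consequence shows up in
prediction: cross-validated predictive intervals for the final-outcome
effect from the network models are roughly half the width of the pooled
model's in such scenarios.

The same analyses run from the shell:

```
bvnma fit --data network.csv --variant 1b --seed 7 --out run/
bvnma crossval --data network.csv --variant 1d --reference-model brma --out cv/
bvnma simulate --scenario 3 --variants brma,1a --reps 20 --seed 1 --out sim/
```

Input tables are delimited text with columns
`study_id, treat_k, treat_l, y1, se1, y2, se2, rho_w` (one row per
two-arm study; empty `y2` marks a missing final-outcome estimate; a
`--rho-w` flag applies one within-study correlation to all rows).  Every
run writes a JSON manifest (variant, priors, seed, chain configuration,
treatment ordering) sufficient to replay it.

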