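# priorpool

Systematically built informative priors for Bayesian cross-lagged mediation
models: expert-weighted power priors, three opinion-pooling rules, a
conjugate Gibbs engine that accepts normal *and* mixture priors, multiple
imputation, and the full diagnostic surface (prior predictive checks,
posterior shrinkage, split-PSR/ESS, HPD intervals, indirect effects).

## The problem

Longitudinal observational studies of parent–adolescent interaction are
expensive, so their samples are small (here: 102 mother–adolescent dyads
with internalizing-symptom composites at waves T1 and T3 and observed
positive/negative interaction behavior at T2). Decades of previous studies
carry relevant evidence, but each previous design matches the new study
only partially. `priorpool` operationalizes a systematic way to borrow that
evidence:

1. **Weight** each previous study with an expert scoring scheme (ten
   categories — longitudinal design, observational assessment, age range,
   …, worth 5–20 points each; maximum 100 for behavior→symptom paths, 80
   for symptom→behavior paths). The score fraction is the power-prior
   weight δ ∈ (0, 1]: a study reporting a standardized effect μ₀ with
   standard error σ₀ enters as N(μ₀, σ₀/√δ) — raising its likelihood to
   the power δ, i.e. dividing its variance by δ. (The alternative σ₀/δ
   convention is available as the `"sd"` dialect.)
2. **Pool** the weighted studies on each parameter:
   - *linear pool* — the equal-weighted mixture Σ wᵢ N(μᵢ, σᵢ), which keeps
     every previous result as-is and can be multimodal;
   - *logarithmic pool* — the normalized product, again normal with
     precision τ = Σ wᵢ/σᵢ² and mean (Σ wᵢμᵢ/σᵢ²)/τ, which keeps only the
     consensual range and is dominated by hyper-precise studies;
   - *fitted normal* — the single normal matching the linear pool's
     moments (or fitted by MLE to draws from it).
3. **Estimate** the two mediation path models

   ```
   behavior_T2 ~ Mint1 + Aint1          (maternal and adolescent behavior;
                                         correlated residuals)
   symptom_T3  ~ M_behavior_T2 + A_behavior_T2 + own symptom_T1
   ```

   by a Gibbs sampler whose full conditionals are all conjugate (normal
   coefficients, a latent component indicator for mixture priors,
   inverse-Wishart for the T2 residual block, inverse-gamma for T3
   residual variances), run per imputed dataset and pooled by
   concatenation. Indirect effects are draw-by-draw products of the
   T1→T2 and T2→T3 paths.
4. **Diagnose**: split-chain PSR and autocorrelation ESS, posterior
   shrinkage s = 1 − σ²posterior/σ²prior, 95% HPD intervals (with a
   union-of-intervals variant for bimodal posteriors), Rubin's fraction of
   missing information, and prior predictive (mean, sd) clouds.

A synthetic-data module generates dyad samples from the published
descriptive moments (with MCAR missingness, including the 54%-missing
depression component) and previous-study evidence fixtures, so everything
runs without the archived study data.

## Worked example

`examples/01_weight_and_pool.py` scores three hypothetical studies of the
maternal symptoms → maternal positive behavior path and pools them:

```
meta_2015    score  30/80  delta 0.375  N(-0.21, 0.082)  (se was 0.050)
cohort_2018  score  50/80  delta 0.625  N(-0.35, 0.152)  (se was 0.120)
cohort_2020  score  45/80  delta 0.562  N(-0.05, 0.120)  (se was 0.090)

linear pool      mixture, mean -0.203, sd 0.172
logarithmic pool N(-0.191, 0.107)
fitted normal    N(-0.203, 0.172)
```

Each study's standard error is inflated by 1/√δ before pooling; the
logarithmic pool is the tightest because multiplying densities discounts
disagreement, while the fitted normal inherits the linear pool's
between-study spread.

`examples/03_fit_and_diagnose.py` runs the whole chain on synthetic data
(packaged evidence → logarithmic priors → 3 imputations → Gibbs) and
prints, among other things:

```
max split-PSR 1.0014   min ESS 2002
 parameter   mean  hpd_lower  hpd_upper  excludes_zero
  MPonMint -0.283     -0.429     -0.129           True
  ...
  MintMPMint   mean +0.066  95% HPD [+0.016, +0.129]
```

i.e. the sampler converges cleanly, higher maternal symptoms predict less
positive maternal behavior a year later, and the first mediated product
(maternal symptoms → maternal positive behavior → maternal symptoms) has a
strictly positive 95% HPD in this synthetic sample.

The other examples cover simulation + imputation (`02`) and the prior
predictive contrast between informative and diffuse priors (`04`).

There is also a thin CLI (`priorpool score|pool|simulate|impute|fit|
diagnose|report|run`) for shell use; `priorpool run --model A --seed 1`
executes the full four-regime sensitivity analysis and writes a report
bundle with a reproducibility manifest.

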