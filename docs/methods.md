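# Methods

This note documents the statistical models implemented in `priorpool`,
the defaults and why they were chosen, what the synthetic data emulate,
and the numerical choices that matter for reproducing results.

## Evidence weighting and power priors

A previous study contributes one standardized effect estimate μ₀ with
standard error σ₀ for one regression parameter. Its design relevance is
scored by a ten-category expert scheme (packaged in
`data/weighting_scheme.yaml`): longitudinal design (10), controlling for
T1 symptoms (20, applicable only to behavior→symptom paths), same 1-year
lag (5), purely observational behavior assessment (15), early-to-mid
adolescent age range (10), internalizing measured as anxiety+depression or
anxiety only (10), partner-symptom and other-behavior covariates (5 each),
community sample (10), meta-analysis (10). Maxima are therefore 100 for
T2→T3 parameters and 80 for T1→T2 parameters, where the change-control
category is meaningless.

The score→δ mapping is not canonical; we default to the linear map
δ = score / max_score and expose it as a pluggable function. δ = 0 (score
0) means "ignore the previous data completely"; rather than assigning an
infinite variance, such studies are dropped with a warning.

For a normal likelihood, raising a study's likelihood to the power δ is
exactly equivalent to dividing its variance by δ, so the default
("variance") dialect sets the prior sd to σ₀/√δ. A second ("sd") dialect
sets it to σ₀/δ, reproducing the convention of dividing the standard
deviation itself; it inflates more aggressively, and the two agree at
δ = 1. Every report records which dialect was used.

## Pooling

With k weighted studies N(μᵢ, σᵢ) on one parameter and equal pooling
weights wᵢ = 1/k (the default; a weights argument exists):

* **linear pool** — the mixture with density Σ wᵢ φ(x; μᵢ, σᵢ), kept
  analytically as a component list (never discretized). Mixture moments:
  mean Σ wᵢμᵢ, variance Σ wᵢ(σᵢ² + μᵢ²) − mean².
* **logarithmic pool** — the normalized weighted geometric mean, which for
  normals is N(m, 1/√τ) with τ = Σ wᵢ/σᵢ² and m = (Σ wᵢμᵢ/σᵢ²)/τ. Its
  variance never exceeds the largest component variance, and a component
  with a tiny sd dominates both its mean and its precision — the mechanism
  by which one hyper-precise previous study can overrule everything else.
* **fitted normal** — `closed_form` mode (default) returns
  N(mixture mean, mixture sd), the infinite-sample limit of a maximum
  likelihood normal fit to pooled draws; it is deterministic and needs no
  seed. `sampling` mode mirrors the simulation procedure (5,000 draws per
  component by default, normal MLE on the pooled draws) and converges to
  the closed form as the draw count grows.

## Path models

Both mediation models have four equations over six roles: T1 maternal and
adolescent internalizing (Mint1, Aint1), T2 observed behaviors (MP2/AP2
positive in model A, MN2/AN2 negative in model B), T3 internalizing
(Mint3, Aint3). T2 behaviors regress on both T1 symptom scores; T3
symptoms regress on both T2 behaviors plus the *own* T1 score (2-year
autoregressive path). The ten slope coefficients are named
`<response>on<predictor>` (MPonMint … AintonAint).

Design choices where the source material is open:

* The two T2 behavior equations form a residual-correlation block with a
  free 2×2 covariance (inverse-Wishart prior, identity scale, df = d+1).
  T3 residuals are modeled as independent — whether the original analysis
  correlated them is unstated, and with both T2 behaviors as shared
  regressors the T3 disturbances are conditionally weakly coupled.
* Intercepts are estimated with the N(0, 10) fallback prior even though
  the data are standardized; this is harmless and keeps the "all other
  parameters" prior statement literal.
* All data are standardized per completed dataset (mean 0, sample sd 1,
  ddof = 1) so coefficients are standardized effects commensurable with
  the priors.

## Gibbs sampler

Every full conditional is conjugate, so no tuning is needed:

* **coefficients** — given all other parameters the likelihood in one
  scalar coefficient c is ∝ exp(ηc − ½λc²) with λ = Ω_kk·xᵀx and
  η = xᵀ(EΩ)_k (Ω the block residual precision; for independent equations
  Ω = 1/σ²). With a normal prior (μ₀, τ₀) the conditional is
  N((η + τ₀μ₀)/(λ + τ₀), 1/(λ + τ₀)).
* **mixture priors** — a latent component indicator is drawn from
  P(z = m) ∝ wₘ · N(η/λ; μₘ, 1/λ + σₘ²) (the exact marginal of the
  conditional), then c from the selected component's conjugate normal.
  The components are fixed densities, not estimated, so no label-switching
  machinery exists or is needed. With a single coefficient and fixed
  residual variance this draw is exact iid sampling from the posterior,
  which is what the grid-oracle test exploits.
* **T2 residual covariance** — inverse-Wishart conditional
  IW(d+1+n, I + EᵀE); the sampler draws the precision matrix directly via
  the Bartlett decomposition.
* **T3 residual variances** — inverse-gamma conditional with prior
  IG(0.01, 0.01), essentially flat on the standardized scale.

Equations are updated in declaration order within each sweep; residuals
are maintained incrementally. Chains are independent `numpy` Generator
streams spawned from one master `SeedSequence`, so identical seeds
reproduce draws bit-identically. Defaults: 3 chains × 8,000 iterations,
3,000 warmup. Each imputed dataset is analyzed separately and the
per-imputation draws are pooled by concatenation; with m = 20, 3 chains
and 5,000 kept draws that is 300,000 pooled draws per parameter.

The emulated **default-prior regime** places N(0, sd = 100) on every
regression coefficient: a proper stand-in for improper flat software
defaults, chosen so that prior variances — and hence shrinkage — remain
defined. This is documented wherever the regime is reported.

## Imputation

Missing cells are completed by joint multivariate-normal data
augmentation rather than chained equations: one coherent model whose
correctness is easy to verify, adequate for continuous composite scores.
Sweeps alternate a posterior draw of (μ, Σ) under the Jeffreys prior
(Σ ~ IW(n−1, S), μ|Σ ~ N(ȳ, Σ/n)) with conditional-normal draws of each
row's missing cells given its observed cells; 100 burn-in sweeps, m
independent streams sub-seeded from the master seed, m = 20 by default.
Observed cells are never touched. The classic >0.10-correlation predictor
rule is honored as a report (`select_predictors`, pairwise-complete
correlations); the joint model conditions on all variables, a superset of
any such selection, which under multivariate normality only adds
information.

## Diagnostics

* **PSR** — classic split-chain R̂ (each chain halved; √(V̂/W) with
  V̂ = (n−1)/n·W + B/n), *not* the rank-normalized variant, matching the
  era of the cited 1.01 threshold that reports surface. PSR and ESS are
  computed per imputed-dataset analysis across its chains; pooling chains
  across imputations would conflate between-imputation variability with
  non-convergence.
* **ESS** — multi-chain autocorrelation ESS: ρ̂ₜ from the between/within
  decomposition, summed in Geyer pairs until the first non-positive pair,
  capped at the total draw count. Constant chains raise a degenerate-draws
  error rather than returning a number.
* **shrinkage** — s = 1 − σ²post/σ²prior with the pooled posterior draw
  variance; for mixture priors the analytic mixture variance is used and
  the row is flagged multimodal, since a variance summary cannot capture
  what a bimodal prior does to a posterior.
* **HPD** — shortest contiguous interval containing ⌈mass·N⌉ sorted
  draws; a histogram-waterline union-of-intervals variant exists for
  bimodal posteriors and is clearly labelled as such.
* **fmi** — Rubin's rules from per-imputation (mean, variance) pairs:
  fmi = (1+1/m)B / (Ū + (1+1/m)B).
* **prior predictive** — for each prior draw, a full dataset of n dyads
  (default 102, the analysis sample size) is simulated through the model
  equations with exogenous T1 predictors standard normal and residual sd
  fixed at 1 on the standardized scale; each dependent variable's (mean,
  sd) pair is recorded, 1,000 draws by default.

## Synthetic data

`generate_dyads` draws from a multivariate normal calibrated to the
published descriptives of the eight composites (means, SDs, and the full
correlation matrix). One printed correlation (maternal negative behavior
T2 with adolescent internalizing T1, −0.81) makes the matrix indefinite
(min eigenvalue ≈ −0.18) and is implausibly large next to every other
symptom–behavior correlation (|r| ≤ 0.3); the packaged spec records the
cell as uncertain and uses the PSD-feasible reading −0.081. Mildly
inconsistent user-entered matrices (min eigenvalue > −0.05) are repaired
by eigenvalue clipping with a warning; anything worse is an error.

Missingness defaults are MCAR at 2–13% per model variable plus 54% on an
auxiliary column representing the depression-questionnaire component of
the T1 adolescent composite (generated with correlation 0.85 to that
composite), so the imputer is exercised realistically. The evidence
fixture generator produces, per parameter, k studies with estimates
N(true effect, se²), se ~ Uniform(0.05, 0.30), and random applicable
category flags; the packaged fixture (`data/synthetic_evidence.csv`,
synthetic — a stand-in for the unavailable study-scoring tables) holds 47
effect-size records across the 16 cross-lagged parameters (15 × 3
studies + 1 × 2). An optional hyper-precise study (se 50× below the range
minimum) recreates the spiked-logarithmic-pool phenomenon.

What the generator does **not** emulate: item-level questionnaire
structure and reliability, attrition or any not-at-random missingness,
and non-normal marginals of the observed composites. Passing tests
therefore demonstrate correctness of the machinery under the stated
moment structure, not robustness to those real-data features.

## Numerical choices and degenerate inputs

Mixture weights must sum to 1 within 1e-12 and be strictly positive;
empty pools, non-positive sds, δ outside (0, 1], masses outside (0, 1),
constant columns under standardization, fully missing columns, and
mismatched parameter sets when pooling imputations all raise explicit
errors. A tiny (1e-12) diagonal jitter guards the generator's Cholesky
factorization at the PSD boundary, and 1e-8/1e-10 ridge terms guard the
imputer's scatter matrix and conditional covariances at small n.
Equation update order is the declaration order; block responses are
processed in sorted order for determinism.

## Problem sizes

Test and acceptance runs use the study-scale settings where the claim is
about those settings (3 chains × 8,000/3,000 on 3 imputations for the
convergence check) and smaller, clearly stated sizes elsewhere: oracle
comparisons use 10⁵–10⁶ draws, parameter recovery n = 5,000 with 2 × 800
kept draws, pipeline round-trips 2 imputations × 2 chains × 300 kept.
These sizes are the package's own verification choices; all of them are
seeded and deterministic.

## Known limitations

* The sampler is a single-site Gibbs scheme; for the models here (few,
  weakly collinear regressors) it mixes essentially like iid sampling,
  but heavy collinearity would slow it — there is no blocked coefficient
  update.
* No latent measurement model and no three-wave fully recursive model:
  behavior is observed once, so mediation is half-longitudinal by design.
* No posterior predictive checks, Bayes factors, or optimality-criterion
  pooling weights (maximum entropy, KL); these are out of scope.
* The >0.10 predictor rule influences reporting only; the joint
  imputation model always conditions on all columns.
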