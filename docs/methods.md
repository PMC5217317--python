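# Methods

## Model and scope

All prediction models are logistic regressions over a shared global
predictor index p = 1..P; a predictor absent from a model has coefficient
zero. The package covers three layers:

1. **Aggregation** of a library of M existing models to a local population
   (stacked regression, PCA regression, PLS logistic regression), each
   reducible to a collapsed intercept-plus-coefficients model on the
   original predictor scale.
2. **Redevelopment** on local data alone (backwards-AIC selection,
   cross-validated ridge), restricted to the union of predictors appearing
   in any existing model — mirroring the practical situation where local
   datasets only collect variables that published models made relevant.
3. A **simulation study** comparing the two strategies across a grid of
   between-population heterogeneity σ and local training size n_train.

## Synthetic data generator

The generator emulates multiple populations that share a predictor
structure but differ in baseline risk and predictor effects.

- **Predictors.** P = 50 variables in 10 clusters of K = 5, representing
  one risk factor measured through several correlated proxy definitions.
  Within a cluster, the first variable is N(0,1); later variables follow
  X_p = ρX_{p−1} + √(1−ρ²)Ψ (continuous clusters) or copy the previous
  latent variable with probability ρ (binary clusters), giving lag-k
  correlation ρ^k. Binary clusters are thresholded at the upper
  `binary_rate` quantile of the latent normal, one rate per cluster drawn
  U(0.10, 0.50). Each cluster is binary with probability 0.5. Default
  ρ = 0.75. All populations' rows are drawn from one matrix, so covariate
  distributions are identical across populations by construction.
- **Outcomes.** Population j uses logit q_ij = α_{0,j} + Σ_p α_{p,j} x_ip.
  Only cluster-start positions (p ≡ 1 mod 5) carry effects:
  α_{p,j} ~ N(ᾱ_p, σ²) there, 0 elsewhere. The mean effects ᾱ_p are drawn
  U(0.80, 1.6) for binary predictors and U(0.08, 0.1) for continuous ones
  (magnitudes typical of published models). Each intercept is solved by
  bracketed root-finding (tolerance 1e−10) so the population's mean event
  probability equals the target rate (default 20%), then jittered by
  N(0, 0.1²) on the logit scale to represent baseline-risk differences;
  the jitter magnitude is a package choice, exposed as `jitter_sd`.
- **Existing model predictor subsets.** The real-world feature being
  emulated is that published models use overlapping subsets of predictors,
  sometimes through proxy definitions. Default scheme, per model and per
  cluster independently: include the cluster-start (true) predictor with
  probability 0.7, else one random proxy from the cluster with probability
  0.2, else nothing. Empty subsets are redrawn. The scheme is configurable
  and serialisable so real predictor sets can be substituted.

What the generator does *not* emulate: non-normal continuous predictors,
mixed clusters, missing data, covariate-distribution shift between
populations, and publication bias in the existing models. Passing tests
therefore demonstrate behaviour under random-coefficient heterogeneity
with identical case mix, not under arbitrary real-world dataset shift.

## Estimation details

- **Plain logistic MLE** goes through statsmodels' Newton solver;
  non-existence of the MLE (perfect or quasi-complete separation,
  divergence beyond |β| = 50) is normalised into a single exception so
  callers can fall back deterministically.
- **Stacked regression** maximises the exact Bernoulli log-likelihood with
  bounds γ_j ≥ 0 (intercept free) by L-BFGS-B with analytic gradients,
  deterministic start γ = (1/M, …, 1/M), γ₀ = 0. As a built-in optimality
  guard the optimum is compared against every single-model recalibration
  (slope ≥ 0) and restarted from the best one if it fails to dominate;
  returned weights are clipped of solver round-off so the constraint holds
  exactly.
- **PCA regression** mean-centres the LP columns before the SVD (no
  variance scaling — the columns share the logit scale) and stores the
  centring constants so the collapsed intercept is exact. All M components
  are kept by default; numerically zero singular values are dropped and
  the reduced rank recorded. With full rank this is prediction-equivalent
  to unconstrained logistic regression on the LP columns.
- **PLS** builds components from the centred working response of one IRLS
  step off the null model (whose weights are constant, so weighted and
  unweighted extraction coincide), deflates, and refits the outcome on the
  retained components by MLE. With all M components it is
  prediction-equivalent to logistic-on-LPs — the class default and the
  tested algebraic anchor — but that limit is also prediction-identical to
  PCA regression and inherits its small-sample overfitting. The simulation
  pipeline therefore selects the component count by stratified 10-fold
  cross-validated binomial deviance (`n_components="cv"`), which typically
  retains one or two components when the existing models are highly
  correlated and restores calibration at small n.
- **Backwards AIC** is greedy single-predictor deletion, accepting a step
  only if AIC strictly decreases; ties below 1e−9 remove the lowest
  predictor index. Separated interim fits fall back to a microscopic ridge
  penalty (λ = 1e−8) and are flagged.
- **Ridge** maximises l* = log L − λΣβ_p² (intercept unpenalised) by a
  damped Newton solver warm-started along a decreasing λ path. Predictors
  are standardised inside each CV training fold (binary columns included)
  so the penalty treats binary and continuous predictors equitably;
  coefficients are returned on the original scale. Raw-scale penalisation
  is available as a toggle. The grid has 100 log-spaced values from a
  data-driven λ_max = max_p |x̃_pᵀ(y − ȳ)| / 0.002 (the ridge-path
  convention of GLM path software) down to 10⁻⁸·λ_max; the deep lower end
  is chosen so the cross-validated deviance minimum is interior to the
  grid rather than clamped at its boundary. λ is chosen by stratified
  10-fold CV deviance (fold count and stratification are package choices).

## Validation measures

- MSE of risks: mean (π̂_i − q_i)² against the generator's true risks on
  the validation set; across iterations it decomposes exactly into
  squared bias plus variance (`bias_variance_decomposition`).
- MSE of coefficients: mean over all P positions (true zeros included,
  intercept excluded) of (β̂_p − α_{p,local})², computed through the
  collapsed representation for aggregates so all methods share a code
  path.
- Calibration slope: coefficient of logit(π̂) in a logistic refit.
  Calibration intercept: the free intercept of a fit with logit(π̂) as a
  fixed offset (calibration-in-the-large), because (0, 1) as the
  well-calibrated reference requires the offset convention; the
  joint-model intercept is available via `joint=True`. Degenerate
  predictions (empty selected model, saturated logits) yield NaN
  calibration fields rather than aborting a scenario.
- AUC: Mann–Whitney with midrank ties (scikit-learn's rank
  implementation; an all-pairs oracle verifies it in tests).
- Iteration summaries report means and empirical SEs (sample SD / √n),
  excluding-and-counting iterations where a measure is undefined (an `n`
  column records the basis of each summary). The between-iteration SD
  (SE × √n) is the relevant yardstick for "is the method well calibrated
  across iterations"; the SE of the mean is what the recommendation rule's
  z-tests use.

## Simulation design and recommendation rule

Each iteration generates 6 populations (5 existing of n_exist = 5000, one
local of n_train + 5000), fits the existing models, splits the local
population at random (degenerate single-class splits are redrawn up to 10
times, then the iteration is rejected and counted), fits SR/PCA/PLS/AIC/
ridge on the training part and scores them on the 5000 validation rows.
Randomness is organised as named independent streams spawned from a
per-iteration seed keyed by (σ, n_train, event rate, iteration index), so
any iteration is re-runnable in isolation and results are independent of
execution order or parallelism.

The recommendation rule compares SR with ridge. A strategy is well
calibrated when its mean calibration intercept lies within the
between-iteration spread of 0 and its mean slope within the spread of 1
(two-sided at α = 0.05 against the empirical SD across iterations).
Calibration is deliberately judged against the spread, not the SE of the
Monte-Carlo mean: against the latter, any fixed offset however small
becomes "significant" as iterations grow, and no method would ever count
as calibrated. The AUC comparison, by contrast, is a genuine comparison of
means and uses a z-test on the empirical SEs of the means. If exactly one
strategy is calibrated it is recommended; if both are, a significantly
higher AUC decides, otherwise "Either". When neither is calibrated (not
reachable in the studied grid) the AUC comparison alone decides — a
package choice for completeness.

## Problem sizes

Reduced-replicate mode (100 iterations) is the default for scenario runs
and the acceptance script; heterogeneity summaries use ≥1000 iterations
(they only draw coefficient vectors and cost milliseconds). Full
1000-iteration grids are supported through `ScenarioConfig(iterations=1000)`.

## Known limitations

- The default predictor-subset scheme is a documented stand-in for the
  (unpublished) predictor sets of real existing models; the location of
  the SR-vs-ridge performance crossover along n_train is sensitive to how
  restricted the existing models' subsets are, so with this scheme the
  crossover can sit at larger n_train than with sparser real-world model
  libraries, even though the qualitative pattern (SR dominant at small n,
  ridge at large n with heterogeneity) is stable.
- The PLS variant is a standard PLS-logistic construction; other PLS-GLM
  flavours (full IRLS reweighting per component, CV component selection)
  would differ slightly below full rank.
- Aggregation assumes every predictor used by an existing model is
  measured locally; systematically missing covariates are out of scope.
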