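# Methods

## Data model and missingness

A cohort is a patients × variables table with typed metadata: binary
variables coded 0/1 (1 = exposed/present), categorical variables stored as
level labels with a declared reference (expanded to reference-coded
indicators only at model time), continuous variables as floats. Missing
values are NaN throughout; there is no imputation. Every analysis stage is
complete-case on exactly the variables it uses: univariable fits on
{variable, outcome}, the multivariable selection chain on the union of all
candidates plus the outcome (fixed once, before elimination, so successive
models are comparable), and each PAR estimator on its own model variables.
Baseline summaries use per-variable complete-case denominators within each
outcome group; the IQR is the 25th–75th percentile with numpy's
linear-interpolation quantile definition.

Dichotomization rules (source variable, threshold, direction) append a
binary exposure column, propagate missingness, and keep the source column.
The shipped defaults are the conventional stroke-cohort cut points: age
≥ 75 years, NIHSS > 4 (moderate-or-worse severity), education ≤ 10 years.
Selection runs on the original coding; dichotomization is applied only
where a binary factor is needed for PAR estimation.

## Firth-penalized logistic regression

The model engine maximizes the Jeffreys-penalized log-likelihood
ℓ*(β) = ℓ(β) + ½·log det I(β). The score of the penalty term gives the
modified score U*(β) = Xᵀ(y − p + h⊙(½ − p)), with h the diagonals of the
weighted hat matrix W^{1/2}X(XᵀWX)^{-1}XᵀW^{1/2}. Fitting is Newton
iteration on U* using the Fisher information as curvature, with
step-halving (factor 0.5, up to 30 halvings) whenever a step would lower
ℓ* by more than a rounding-level slack of 1e-10·max(1, |ℓ*|); without that
slack the iteration can stall one float above the optimum and flag a
spurious non-convergence. Convergence requires max|U*| ≤ 1e-6 (a
max|Δβ| ≤ 1e-8 step is a secondary stop, and the convergence flag is still
tied to the score criterion); the iteration cap is 100, and a capped fit
is returned flagged, never silently. Rank-deficient designs are an error,
not a silent column drop. The reported covariance is the inverse Fisher
information at the optimum. These constants are fixed and exposed as
estimator parameters.

Inference conventions:

- **Likelihood-ratio tests** compare the full fit against the full model
  profiled with the tested coefficients constrained to zero, *keeping the
  full model's penalty* — the convention of reference Firth
  implementations. The superficially simpler alternative (each model's
  penalized likelihood at its own optimum) leaves a dimension-dependent
  ½·log det I remainder in the statistic; measured on 400 null data sets
  of n = 50 it rejected at ~9.7% for nominal 5%, while the profile
  convention sits at the nominal level (the calibration is asserted over
  1,000 null simulations in the test suite).
- **Confidence intervals** default to profile penalized likelihood
  (signed-root crossing found by bracketed Brent search, expanding from
  the Wald step; endpoints beyond ±10 log-odds are an error), which makes
  the test and interval dual. Wald intervals exp(β ± z·se) are available
  and are what the pipeline's adjusted-OR report uses.
- **VIF** for column j is 1/(1 − R²_j) from an OLS regression of that
  column on the other non-intercept columns plus an intercept; constant
  or perfectly collinear columns report infinity. The pipeline flags
  VIF > 10.

On any saturated 2×J model the Firth fit coincides with the half-unit
cell augmentation of the contingency table, which is what lets published
univariable odds ratios be reproduced exactly from printed counts.

## Variable selection

Screening fits each candidate univariably and keeps those with block
penalized-LRT p < 0.1 (a variable with a single observed level is flagged
inestimable and never selected). Backward elimination then repeatedly
removes the variable with the largest block p ≥ 0.05, ties broken by
removing the later variable in input order, until all survivors are below
the stay level; categorical variables enter and leave as whole indicator
blocks. Both thresholds are configuration defaults, not constants.

## The three PAR estimators

All three target "the proportion of events prevented if exposure(s) were
removed", but operationalize it differently:

- **Combined AF (Bruzzi form, default)**: over cases only,
  AF(S) = 1 − (1/n₁)·Σ exp(η_i(S→0) − η_i), where η is the linear
  predictor of one multivariable Firth fit and S→0 zeroes the columns of
  the factors in S. This is an odds-ratio-based formula, exact under a
  rare outcome. The **g-computation** form
  AF(S) = 1 − Σ p̂(η_i(S→0)) / Σ p̂(η_i) over all subjects is preferred
  when the outcome is common (the suite checks the two agree within 0.01
  once incidence is pushed to ~1% with odds ratios held fixed). No
  refitting between eliminations: every subset AF re-evaluates the single
  fitted model's predictions (`refit=True` exists for sensitivity
  analysis). Sequential contributions along an ordering telescope to the
  full-set AF by construction.
- **Coughlin's per-factor PAR** is the first-removal sequential
  contribution, AF({f}) from the multivariable fit. Under positive
  dependence between factors it over-credits each factor with the shared
  multimorbidity burden: since
  AF(S∪{f}) − AF(S) = mean_cases[exp(−β_S·a_S)(1 − exp(−β_f·a_f))], every
  later-position contribution is bounded by the first-position one
  whenever coefficients are nonnegative, so Coughlin ≥ average PAR per
  factor, with equality only in degenerate cases (k = 1 or vanishing AF)
  — *not* under mere independence of the factors.
- **Average PAR** is the Shapley value: enumeration over k! orderings
  (k ≤ 10) or the weighted subset sum with w(S) = |S|!(k−|S|−1)!/k!
  (k ≤ 20); the two routes agree to 1e-12 and are used as mutual oracles.
  Shares sum to the full-set AF (efficiency) and are order-invariant.
- **Doubly robust PAR** estimates E[Y(0_f)] by AIPW:
  mean(m̂(0,C) + (1−A)(Y − m̂(0,C))/(1 − π̂(C))), with both nuisance
  models Firth-logistic. 1 − π̂ is floored at 0.01 (clips counted and
  logged; all-clipped is a positivity error), and the final mean is
  truncated into [0, 1] with a warning — AIPW is not range-respecting by
  construction. The estimand is the single-factor (first-removal) PAR; no
  doubly robust *sequential* scheme is defined here, since there is no
  canonical way to order AIPW removals, and the comparison table
  documents the estimand per column instead. Each nuisance model can be
  given its own covariate set, which is how the test suite verifies the
  defining robustness property (consistency with either model garbled).

`compare_methods` reports all three per factor with dense descending
ranks; a nonparametric patient-resampling bootstrap (seeded, configurable
B) provides percentile intervals as optional plumbing.

## Synthetic cohorts and exact truths

Two joint exposure models:

- **Explicit pmf** over all 2^k profiles (factor j in bit j). Truths are
  exact finite sums: E[Y] and E[Y(S→0)] are pmf-weighted sums of the
  logistic risk over the 2^k profiles, so true AF, true sequential
  contributions, and true Shapley shares are available to machine
  precision. A pairwise exponential-tilting constructor (`tilted_pmf`)
  produces positively dependent factors from independent base weights.
- **Gaussian copula**: factor j is 1 when its latent normal (correlation
  matrix R) exceeds the 1 − p_j quantile, giving exact marginals with
  latent-scale dependence. Truths for this variant are Monte Carlo only;
  exact orthant probabilities are deliberately not attempted because the
  pmf variant covers every exact-truth need.

Outcomes are Bernoulli(expit(β₀ + Σ β_f A_f)); missingness is independent
per cell at per-variable rates. All randomness derives from one seed via
`SeedSequence(seed, spawn_key=(stream,))` with a fixed stream per logical
draw (exposures, outcome, one per variable's missingness), so adding
missingness or variables never perturbs earlier draws, and identical
spec + seed reproduces tables exactly.

The **preset cohort** mimics a first-stroke population: five binary
factors — age ≥ 75 (prevalence 0.284, OR 2.6), pre-stroke disability
(0.183, 3.0), NIHSS > 4 (0.237, 2.0), education ≤ 10 years (0.30, 1.8),
diabetes (0.215, 1.8) — with a single exchangeable latent correlation of
0.3, chosen so that most poor-outcome patients are multiply exposed; 1%
missingness per factor. The intercept −2.5372 was solved once from 2×10⁶
latent draws so expected incidence is 0.205. Prevalences for four factors
are cohort margins; the education prevalence and all effect sizes are
documented stand-ins of realistic magnitude, not reconstructions — the
real joint distribution and adjusted effects of any particular cohort are
unknown. Consequently the preset supports *structural* and *statistical*
claims (calibration, recovery, dominance patterns, selection power), not
numerical reproduction of any published PAR table.

What the generator does not emulate: continuous risk-factor distributions
(beyond what dichotomization tests need), informative or correlated
missingness, unmeasured confounding, interactions or non-logistic risk
surfaces, and time-to-event structure. Passing recovery tests therefore
show the estimators are correct *under their stated assumptions*; they do
not certify behavior under model misspecification beyond the specific
garbled-nuisance scenarios tested.

## Problem sizes used in validation

The suite validates parameter recovery on pmf cohorts of k = 3, n = 20,000
over 100 seeds (g-computation average PAR) and 40 seeds per
doubly-robust misspecification scenario, comparing the mean estimate to
the exact truth within three empirical standard errors of that mean;
penalized-LRT calibration on 1,000 null data sets of n = 50; null
backward-selection retention on 200 replicates of n = 300; and selection
power on 200 preset replicates of n = 5,000. These sizes were chosen so
sampling error is small relative to the effects under test while the full
suite stays fast.

## Known limitations

- PAR interpretation assumes the fitted associations are causal and
  removable; residual confounding inflates every estimator alike.
- The Bruzzi form is biased away from the g-computation form when the
  outcome is common (~20% incidence); both are reported, tagged by
  method.
- The doubly robust column estimates a different functional than the
  model-based columns whenever the factors interact in the data; ranks
  are comparable, magnitudes only approximately.
- Profile intervals are searched within ±10 log-odds; pathological
  near-degenerate tables whose bounds lie beyond that raise rather than
  extrapolate.
- `exact_enumeration` truths require the pmf variant; copula truths carry
  Monte Carlo error reported through the chosen `mc_n`.
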