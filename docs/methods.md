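# Methods

This note documents the statistical model, the estimation procedure, the
synthetic-cohort generator, the numerical choices, and the limitations of
`trialtransport`. Notation: `T` event time, `C` censoring time, `A ∈ {0,1}`
treatment (1 = intensive regime), `X` baseline covariates, `S` selection
(1 = trial, 0 = target), `t*` the risk horizon.

## 1. Estimand and identification

The estimand is the counterfactual `t*`-year risk contrast in the target
population:

    risk_a = E[ 1{T^a ≤ t*} | S = 0 ],   RR = risk_1 / risk_0,   RD = risk_1 − risk_0.

Identification uses the standard transportability conditions:

1. **Randomization in the trial** — `A ⊥ T^a | X, S = 1`.
2. **Conditional exchangeability over selection** — `T^a ⊥ S | X`: the
   covariates carried into the model capture every outcome-relevant
   difference between trial and target.
3. **Positivity of selection** — every covariate pattern with positive
   density in the target also occurs in the trial.
4. **Consistency / no interference** and correctly specified outcome model.

Under 1–4 the g-formula (outcome-model) estimator is consistent: fit the
outcome model within each trial arm, predict each **target** subject's
risk under both arms, and average. No selection or treatment weights are
used; conditions 2–3 are untestable and must be argued substantively. The
package reports two diagnostics in their support: standardized mean
differences between cohorts (condition 2 plausibility) and the count of
target subjects outside the trial's observed covariate range (condition 3,
where predictions are model extrapolations).

## 2. Outcome model: flexible parametric survival

Each arm's model is a spline-based proportional-hazards survival model on
the log cumulative hazard scale:

    log H(t | X) = s(u; γ) + X′β,   u = log t,

where `s(u; γ) = γ₀ + γ₁ u + Σⱼ γⱼ₊₁ vⱼ(u)` and `vⱼ` is the restricted
cubic (natural) spline basis

    vⱼ(u) = (u − kⱼ)₊³ − λⱼ (u − k_min)₊³ − (1 − λⱼ)(u − k_max)₊³,
    λⱼ = (k_max − kⱼ) / (k_max − k_min),

which is linear beyond the boundary knots — so extrapolation of the
baseline hazard beyond the observed follow-up is log-log-linear, i.e.
Weibull-tailed, not cubic. With zero internal knots the model **is** the
Weibull model, which the test suite exploits as a closed-form oracle
(comparison against an independent Weibull maximum-likelihood fit).

The right-censored log likelihood is

    ℓ(γ, β) = Σᵢ dᵢ [ ηᵢ + log(∂s/∂u)(uᵢ) − log tᵢ ] − Σᵢ exp(ηᵢ),

with `ηᵢ = s(uᵢ) + xᵢ′β` and `dᵢ` the event indicator. It is maximized by
BFGS with the analytic gradient; see "Inference and numerics" below for the safeguards.

Knots: boundary knots at the minimum and maximum log **event** times;
internal knots at event-time log centiles (e.g. the 33rd/67th for two
internal knots). Default: 2 internal knots, a standard choice that tracks
non-monotone hazards without overfitting typical trial-sized arm samples.

Fitted `H` must be non-decreasing in `t`. Because covariates enter
proportionally they cannot break monotonicity, so the check is on the
baseline spline alone, over a fine grid of the observed time range; a
violation triggers an automatic refit with one fewer internal knot (with a
warning), terminating at the always-monotone Weibull.

## 3. Transport procedure

1. **Eligibility.** Ordered rules (`<, <=, >, >=, =, in-set, in-range`)
   filter the target; each rule reports its removals. Rows with missing
   values in a rule variable are excluded or kept per rule (`on_missing`).
2. **Comparability.** SMD table trial vs. target:
   `(m₁ − m₂)/√((s₁² + s₂²)/2)` for continuous variables,
   `(p₁ − p₂)/√((p₁(1−p₁) + p₂(1−p₂))/2)` for binary, per-level for
   categorical; pairwise deletion of missing values; `|SMD| > 0.1` flagged
   as meaningful.
3. **Arm models.** Fit the survival model above separately in each trial arm on the
   chosen covariates.
4. **Standardize.** Average the predicted `t*`-risks over the (eligible)
   target rows; form RR and RD.
5. **Trial benchmark.** The same model with treatment as the sole
   covariate, standardized over the trial, gives the trial RR/RD.
6. **Agreement.** The transported point estimate "agrees" when it lies in
   the closed 95% bootstrap CI of the trial estimate. This is a
   compatibility screen, not an equivalence test: it inherits the trial
   CI's width and does not account for the transported estimate's own
   uncertainty.
7. **NNT/NNH.** `round(1/|RD|)`; NNT when RD < 0 (treatment reduces
   risk), NNH when RD > 0. RD exactly 0 raises an error rather than
   reporting an infinite NNT.
8. **Subgroups.** Defined by eligibility rules on the target. By default
   the full-trial arm models are reused and only the standardization
   population changes (stable, assumes no subgroup-specific model
   misspecification); `restrict_trial=True` instead refits the models on
   the trial subgroup.

## 4. Missing covariates: FCS multiple imputation

Trial and target are stacked and imputed jointly by fully conditional
specification (chained equations), so target imputations borrow the
trial's covariate-outcome relationships and vice versa:

- Auxiliary columns in every conditional model: `_S` (selection
  indicator), `_A` (treatment; 0 for target rows), and `_naH` (the
  Nelson–Aalen cumulative-hazard estimate of the outcome evaluated at the
  subject's own follow-up time; 0 for target rows) — the standard way to
  carry survival-outcome information into imputation models. Arm and
  outcome availability coincides exactly with `S = 1`, so `S` is the sole
  availability indicator; separate per-column indicators would be
  perfectly collinear with it.
- Conditional models with proper posterior draws: Bayesian linear
  regression for continuous variables (σ² from the scaled inverse-χ²
  draw on the residual sum of squares, then β ~ N(β̂, σ²(X′X)⁻¹)),
  logistic regression with a normal draw on the coefficient covariance
  for binary variables (falling back to the observed margin when the fit
  separates), multinomial logit for categorical.
- Variables are imputed in increasing-missingness order; initial fills are
  draws from each variable's observed margin; the default is 10 cycles and
  `m = 10` completed datasets. Observed cells are never altered.
- Pooling: the pooled RR is the arithmetic mean of the per-imputation RRs
  (a geometric/log-scale mean is available behind a flag); RDs and risks
  pool arithmetically.

When nothing is missing, imputation degenerates to `m` identical copies
(with a warning) and the nested bootstrap below collapses exactly — bit
for bit — to a plain percentile bootstrap.

## 5. Inference and numerics

**Nested bootstrap.** For each of `B` replicates: resample the trial (and,
by default, the target) with replacement; impute `m_within` times within
the replicate; transport on each completed dataset; pool. Percentile CIs
use the closest-observation empirical quantile (`np.quantile(...,
method="closest_observation")`), so `B = 2` yields exactly (min, max) and
at production sizes (defaults: `B = 1000` trial / `B = 500` transported)
it is indistinguishable from interpolated percentiles.
Replicates whose model fit fails (e.g. a resample with too few events) are
skipped; more than 10% skipped aborts with an error instead of quietly
reporting a CI from a biased subset. Seeding uses
`numpy.random.SeedSequence(seed).spawn(B)`, giving independent substreams
per replicate and bit-reproducible results for a fixed seed.

**Monte-Carlo SE for imputation checks.** The variance of the pooled MI
estimate in excess of the complete-data estimate is Rubin's
missing-data component `(1 + 1/m) B̂`, with `B̂` the between-imputation
variance of the per-imputation estimates; the within-imputation sampling
variance is shared by both estimates and cancels from the contrast. The
consistency tests use `3·√((1 + 1/m) B̂)` as the tolerance.

**Likelihood safeguards.** The log-likelihood term `log(∂s/∂u)` is
undefined when the spline slope approaches zero during optimization; below
a floor of `1e-8` the log is continued linearly (first-order Taylor
extension), keeping the objective and gradient finite and smooth without
changing the optimum when the final fit is monotone. Optimization starts
from the exponential-model solution (`γ = (log event rate, 1)`, `β = 0`),
which is already the MLE's scale. Fits require at least 10 events per arm;
fewer raises a fit error rather than returning an unstable model.

**Simulation sizes in the test suite** (package choices, tuned to keep the
suite under a few minutes while leaving comfortable statistical margins):
oracle-recovery studies use 50 repetitions at trial n = 2000 / target
n = 5000 with tolerances ±0.05 (RR) and ±0.01 (RD) on the mean error;
coverage studies use 100 repetitions of trial n = 500 with `B = 100` and a
Weibull (0-internal-knot) working model, accepting 85–100 hits where the
binomial 99.9% band around 95% coverage is roughly 87–100.

## 6. Synthetic cohort generator

The generator exists to provide a truth oracle, not to be demographically
faithful. It emulates:

- Weibull proportional-hazards event times,
  `H(t|X,A) = λ t^k exp(X′β + A(θ + X′δ))`, sampled by inversion; `δ`
  gives treatment-covariate interactions so the transported effect can
  genuinely differ from the trial effect.
- Independent exponential dropout plus administrative censoring at the
  horizon (default 4 years).
- Targets as covariate-shifted versions of the trial distribution
  (mean shifts for continuous, probability overrides for binary/
  categorical), optionally with Gaussian-copula correlation.
- MCAR and MAR missingness; MAR probabilities follow a logistic model in a
  driver covariate whose intercept is solved numerically (Brent's method)
  so the requested marginal missing fraction holds exactly in expectation.
- A preset (`presets.sprint_ckd_dgp`) whose trial marginals match
  published SPRINT CKD-subgroup baseline summaries and whose target shift
  matches the published VHA CKD cohort, with the baseline scale calibrated
  to an 8% 4-year standard-arm risk. One published value (the VHA eGFR SD)
  was implausible as printed and is replaced by a clinically plausible
  value, noted in the preset source.

It deliberately does **not** emulate: time-varying treatment or adherence,
competing risks, informative censoring, measurement error, clustering by
site, or non-proportional hazards. The closed-form oracle
(`oracle_true_risks`, `oracle_true_effect`) integrates the true risk over
the realized target covariates, so estimator tests compare against exact
truth rather than a second Monte-Carlo approximation.

Reproducibility: every random stream is a `default_rng` keyed on the
config seed plus a purpose constant plus (for targets and missingness) a
CRC-32 hash of the population id, so trial, target and missingness draws
are mutually independent and stable across runs and platforms.

## 7. Tunable parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| `horizon` | 4.0 | years | Matches the published SPRINT CKD transport analyses. |
| `n_internal_knots` | 2 | knots | Flexible yet stable at trial-arm sizes; auto-reduced on non-monotone fits. |
| trial bootstrap `B` | 1000 | replicates | Percentile-CI stability for the benchmark estimate. |
| transported bootstrap `B` | 500 | replicates | Imputation nesting multiplies cost; 500 keeps quantile error well below reported precision. |
| `m_within` | 10 | imputations | Standard MI practice at moderate missingness. |
| `n_cycles` | 10 | FCS sweeps | Chained equations typically converge in 5–10. |
| `max_skip_fraction` | 0.10 | fraction | More failed replicates than this signals a data problem, not noise. |
| `MEANINGFUL_SMD` | 0.1 | SMD | Conventional imbalance threshold. |
| `on_missing` (eligibility) | exclude | — | Conservative: unknown eligibility is treated as ineligible. |
| NNT rounding | nearest integer | patients | Matches the published worked examples. |

## 8. Open design decisions and limitations

- **Outcome-model transport only.** No inverse-odds-of-selection
  weighting or doubly robust estimator is provided; correctness leans
  entirely on the outcome model. The extrapolation count is the only
  positivity diagnostic.
- **Agreement is descriptive.** Point-in-CI is asymmetric (wide trial CIs
  make everything "agree") and is reported as a screen, not a test.
- **Proportional hazards within arm** is assumed; arm-specific fits allow
  non-proportionality *between* arms but not within.
- **Bootstrap cost.** The nested (impute-within-replicate) bootstrap is
  `B × m_within` transports; for very large cohorts users may prefer fewer
  imputations per replicate, trading MI efficiency for wall time.
- **FCS congeniality.** Linear/logistic conditionals may be uncongenial
  with the spline outcome model; the Nelson–Aalen auxiliary mitigates but
  does not remove this.
- **Pooling scale.** RRs pool arithmetically by default for
  interpretability; log-scale pooling is available and preferable when
  per-imputation RRs vary over orders of magnitude.
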