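# Methods

## Estimands

For one binary belief item, let `A` indicate the declared "exposed" belief
state, `Y` the binary behavioral intention, and `Y_a` the potential outcome
under exposure level `a`. The screen's estimand is the
population-attributability

```
PA = Pr(Y=1) − Pr(Y_0=1) = {Pr(Y_1=1|A=1) − Pr(Y_0=1|A=1)} · Pr(A=1),
```

the product of the causal risk difference *in the exposed* and the exposure
prevalence. The PAF divides PA by `Pr(Y=1)`.

Two identification routes are implemented:

* **crude** — assumes unconditional exchangeability (`Y_a ⫫ A`), giving
  `ΔY = Pr(Y=1|A=1) − Pr(Y=1|A=0)` from the 2×2 table;
* **msm** — assumes conditional exchangeability given the measured
  categorical confounders (`Y_a ⫫ A | X`) plus consistency and positivity.
  The propensity `e(x) = Pr(A=1|X=x)` is fitted by main-effects logistic
  regression on the dummy design (intercept; one indicator per non-reference
  level, in declared order). ATT odds weights `w = e(x)/(1−e(x))` are applied
  to the unexposed (`w ≡ 1` for the exposed), and the saturated weighted
  linear-probability model `Pr(Y=1|A=a) = β₀ + β₁a` is fitted by weighted
  least squares; `β₁` is the adjusted ΔY. Because the model is saturated,
  `β₁` equals the weighted exposed/unexposed outcome-mean difference exactly,
  and the fitted values cannot leave [0, 1] — the identity-link hazard of
  out-of-range predictions does not arise (asserted, not corrected).

## Inference

* Crude `SE(ΔY)` is the unpooled Wald form
  `sqrt(p₁(1−p₁)/n₁ + p₀(1−p₀)/n₀)`; `SE(p) = sqrt(p(1−p)/n)`.
* The MSM `SE(β₁)` is the weight-fixed HC0 sandwich
  `(X'WX)⁻¹ (Σ wᵢ² rᵢ² xᵢxᵢ') (X'WX)⁻¹` — the robust variance a GEE routine
  with identity link and independence working correlation reports. The
  closed-form WLS point estimate is algebraically identical to that routine's;
  the closed form was chosen for transparency and testability. Weights are
  treated as known constants: uncertainty from the propensity fit is *not*
  propagated, by design. The suite verifies the sandwich against
  `statsmodels` WLS/HC0 (1e-12) and against a nonparametric bootstrap that
  refits the propensity per replicate (agreement within 15% on a confounded
  two-stratum cohort, n = 2000, 2000 replicates).
* `SE(ΔY·p)` is the first-order delta method under approximate independence
  of the factors, `sqrt(ΔY²SE(p)² + p²SE(ΔY)²)`; the dependence between the
  two estimators is ignored, as documented, not corrected. 95% CIs use the
  literal critical value 1.96 (matching printed-table convention) and
  p-values are two-sided normal on PA itself. With `SE = 0` the p-value is
  defined as 0 for nonzero PA and 1 otherwise.
* PAF is reported as a point estimate only; no interval is invented for it.
* Across many beliefs the default report flags raw `p < 0.05`; an optional
  Benjamini–Hochberg column (`bh=True`) is available but off by default.

## Numerical choices

* Logistic fitting is Newton–Raphson with step-halving; convergence when the
  score's max absolute entry < 1e-8 or the relative log-likelihood change
  < 1e-10, capped at 100 iterations, followed by up to three polish steps
  that drive the score toward machine zero. The polish matters because the
  saturated-equivalence oracle (below) is asserted at 1e-10.
* Separation (any fitted propensity within 1e-8 of 0/1 with coefficient
  sup-norm above 30) is a hard error naming the offending covariate pattern;
  no ridge penalty is applied, since silently regularizing would change the
  estimand mid-screen. Such beliefs appear in the report's inestimable list.
* An unexposed respondent with fitted propensity within 1e-12 of 1 is an
  error (infinite weight). Weight truncation (`weight_cap`) exists as an
  explicit opt-in flag and is never applied by default.
* Two-decimal display values use round-half-even. Full-precision columns are
  authoritative: a displayed product can differ by 0.01 from the product of
  its own two rounded factors.
* Ties in the PA ranking are broken lexicographically by belief id.

## Input handling

* Binary columns accept {0/1, yes/no, true/false} spellings,
  case-insensitive; the configuration's `exposed_level` fixes which state is
  A = 1. Signs are never auto-flipped: PA is reported signed, and orientation
  of each item is the analyst's declaration.
* Rows with missing values in any declared column are dropped with a logged
  count; a confounder may instead declare a "did not respond" level, which
  is then an ordinary category (this is also the default treatment of
  household income in the study-shaped generator). No imputation.
* A declared binary column with more than two observed values, an unseen
  confounder level, or an empty file is a validation error.

## Synthetic cohorts and what they show

The generator draws a joint confounder stratum `x ~ π`, exposure
`A ~ Bernoulli(expit(α₀ + α₁'d(x)))` on the dummy design, and both potential
outcomes `Y₀ ~ Bern(m₀(x))`, `Y₁ ~ Bern(m₁(x))`, observing `Y = Y_A`.
Consistency and conditional exchangeability hold by construction, and all
estimands are exact stratum sums (no integration): the per-stratum
counterfactual parameterization was chosen precisely so truth is enumerable.

The default study-shaped specification mirrors the survey the package was
designed around: five categorical confounders (age group 2 levels, education
3, employment 3, household income 4 including "did not respond", marital
status 2; joint distribution the product of the published marginals), one
belief with prevalence 0.84, outcome rate 0.134, and a constant
counterfactual risk difference of 0.08 (so the true ATT ΔY is 0.08 and true
PA = 0.0672). Intercepts are solved by root-finding so prevalence and outcome
rate hold exactly in the population; the slopes on exposure and baseline risk
share signs, producing upward confounding of roughly +0.015 in the crude PA
at the default strength. A `confounding=0` variant makes the propensity
constant.

What passing tests do and do not show: the generator has independent
confounders, a single belief per dataset, a correctly specified main-effects
propensity model, and no missing data or measurement error. Calibration
results under it (unbiasedness of the MSM route, ~95% CI coverage) therefore
demonstrate internal correctness of the estimators, not robustness to
propensity-model misspecification, correlated belief batteries, informative
non-response, or unmeasured confounding — none of which the method claims to
handle (no sensitivity analysis for unmeasured confounding is included).

Randomness discipline: one seeded `numpy` generator per `simulate` call;
Monte-Carlo replicate `r` uses `seed + r`.

## Test problem sizes

The oracle hierarchy, from exact to stochastic: hand-arithmetic fixtures;
a dense grid-search MLE for the logistic fit; the G-formula standardization
(`standardize_att`) which must equal the weighted-MSM coefficient to 1e-10 on
1000 random saturated single-confounder fixtures; Monte-Carlo checks of
generator truth at n = 10⁶; and estimator-calibration runs at n = 5000 with
500 replicates (bias) and 1000 replicates (coverage, accepted within
[0.93, 0.97]). These sizes make the full suite run in well under a minute.

## Known limitations

* The delta-method CI assumes approximate independence of ΔY and p and
  asymptotic normality; both are inherited assumptions, kept deliberately.
* The robust SE ignores propensity-estimation uncertainty (matching the
  two-stage procedure it implements); the bootstrap comparison shows the
  effect is small in the settings tested, not in general.
* ATT odds weighting targets the risk difference in the exposed; no
  stabilized full-population IPW estimand is provided.
* Exact small-sample inference (Fisher, Clopper–Pearson) is out of scope:
  the screen is Wald/asymptotic throughout.
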