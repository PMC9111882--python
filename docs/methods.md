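# Methods

## The effect size

The unit of analysis is one survey estimate of self-reported drinking
change. Among the study's `n` current drinkers, `n_inc` report increased
and `n_dec` decreased consumption; the change score is
`d = (n_inc − n_dec)/n ∈ [−1, 1]`. Treating the three answers
(increase, decrease, no change) as one multinomial draw, the variance of
the difference of the two paired proportions is
`Var(d) = [p_inc + p_dec − (p_inc − p_dec)²]/n`, whose plug-in estimate is
the closed form

    SE = (1/n) · sqrt(n_inc + n_dec − (n_inc − n_dec)²/n).

This is exact under the multinomial model, not a delta-method
approximation; the test suite confirms it against the empirical SD of
simulated studies to well under 2% relative error.

Prevalence-of-use changes (drinking at least weekly/monthly before vs
during the observation window) reuse the same formulas on the discordant
cells — respondents who started (`n_start`, counted as increases) or
stopped (`n_stop`, decreases) drinking. When a study reports only the two
marginal prevalences, the difference is `p_during − p_before` with
`SE = sqrt((p_during + p_before − d²)/n)`. This substitution drops the
(unobserved) pairing covariance and therefore overstates the SE when
before/during status is positively correlated, which it typically is; such
estimates are flagged `approximate_se` in every output.

Estimates with `SE = 0` (no changers at all, or |d| = 1) carry no
information for inverse-variance pooling and are excluded with a logged
warning before fitting.

## Data preparation

- **Drinker denominators.** Surveys reporting only a total sample size get
  `n = round(n_total × prop_drinkers)`, further multiplied by the share of
  women (or men) for gender-stratified rows; surveys without a drinker
  proportion fall back to `n = n_total`. Rounding is half-up so counts stay
  integers; the choice is immaterial at survey sizes (hundreds to tens of
  thousands) and is recorded in each record's provenance.
- **Starters/stoppers.** Where reported, they widen the denominator
  (`n += n_start + n_stop`) and are folded into the increase/decrease
  counts. The pre-fold counts are preserved in provenance.
- **Monthly waves.** Studies reporting monthly change proportions are
  collapsed into the three pre-defined pandemic periods (P1 March–June
  2020, P2 July–September 2020, P3 October 2020 or later) by unweighted
  averaging of the monthly proportions; counts are rebuilt from the
  period-mean denominator. A study spanning two periods contributes one
  record per period.
- **Subsets.** Records are grouped by indicator (overall use, drinking
  frequency, quantity per occasion, heavy episodic drinking, prevalence of
  use) and stratum. The total-sample analysis uses a study's total row
  where present; studies reporting only gender-stratified rows contribute
  both rows as separate estimates (this is the only rule that reproduces
  the canonical 52-estimates-from-44-studies bookkeeping of this
  literature). A subset is pooled only when it draws on at least five
  independent studies.

## Random-effects model

`d_i = μ + u_i + ε_i` with `u_i ~ N(0, τ²)` and `ε_i ~ N(0, SE_i²)` (known).
τ² is estimated by REML — Fisher scoring on the profiled restricted
likelihood, started from the DerSimonian–Laird value, with step-halving,
non-negativity projection, convergence tolerance 1e-8 and a 200-iteration
cap, falling back to bounded scalar maximisation of the restricted
log-likelihood if scoring stalls. The DL moment estimator (truncated at 0)
is retained as an alternative and as an oracle cross-check. Inference is
Wald: `z = μ̂/SE(μ̂)`, 95% CI `μ̂ ± 1.959964·SE(μ̂)` — not Knapp–Hartung,
matching the defaults of the reference R implementation, against which the
fits agree to ≤ 1e-6 in the test suite.

Heterogeneity: Cochran's Q with fixed-effect weights around the
fixed-effect mean, referred to χ²(k−1); I² primarily as
`100·τ²/(τ² + s²)` with the typical within-study variance
`s² = (k−1)Σw/((Σw)² − Σw²)`, `w = 1/SE²`; the (Q−df)/Q form is reported
alongside as `I2_q`.

## Moderator meta-regressions

One categorical moderator at a time enters as dummy-coded fixed effects
with residual τ² re-estimated by REML under each model (the same profiled
machinery handles an arbitrary design matrix). Reference levels: period P1,
age profile "general", unweighted, Western Europe. The omnibus moderator
test QM is a Wald chi-square on the non-intercept coefficients (χ² rather
than F, again the reference-software default). Level means are linear
combinations `Lβ̂` and are invariant to the reference-level choice. Because
four moderator models reuse the same estimates, significance is judged at
the Bonferroni-corrected threshold α/4 = 0.0125 by default.

## Small-study bias

The primary Egger variant regresses `d` on its SE inside the mixed-effects
framework, τ² re-estimated under the bias model; the slope's
`t = β̂₁/SE(β̂₁)` is referred to Student t with k−2 df, following the
convention of this literature's summary tables (the reference software's
own default p-value uses a normal reference; the statistic is identical).
The classical variant — WLS of `d` on SE with weights 1/SE² and estimated
residual scale, equivalent to OLS of `d/SE` on `1/SE` — is available as a
cross-check. Funnel exports give (d, SE) points plus pseudo-95%-CI contour
lines `μ̂ ± 1.96·SE` over the observed SE range.

## Leave-one-out

The model is refitted k times, omitting one estimate each. An omission is
flagged as influential when the reduced-model pooled estimate leaves the
full-model 95% CI or when it flips the significance of the pooled effect
at α = 0.05. Note that omitting a single gross outlier often does *not*
move the pooled estimate outside the full CI — the outlier inflates τ² and
hence its own CI — so the significance-flip criterion does most of the
work in practice.

## Synthetic-data generator

The generator emulates the study-level structure the analysis assumes,
parameterised on the change-score scale. With churn `c` (expected share of
drinkers reporting any change) and study effect
`θ_i = μ + moderator shifts + N(0, τ²)`:

    p_inc = (c + θ_i)/2,   p_dec = (c − θ_i)/2,

so `E[d_i] = θ_i` and `p_inc + p_dec = c`; responses are one multinomial
draw per study. Configurations must satisfy `|μ| + 3τ ≤ c` so implied
probabilities stay in the simplex; a moderator-level combination that
systematically leaves the simplex by more than 0.01 is a configuration
error, while rare tail draws of `θ_i` (probability ≈ 4e-4 per study at the
defaults) are clipped to the boundary with a counted warning.

Defaults are the study conditions of the European pandemic
drinking-change literature: 44 surveys; grand mean μ = −0.038 (the pooled
overall change score reported there); churn 0.5; τ = 0.14, which at these
survey sizes puts I² near 99% as observed; drinker denominators log-uniform
on [300, 20000] (totalling ≈ 190k drinkers); three-quarters of surveys in
period P1; 45% weighted; roughly half convenience samples. Optional
features: starters/stoppers drawn binomially at configurable rates, and a
selection (suppression) function of (d, SE) for funnel experiments, under
which generation resamples until k studies are retained.

What the generator does **not** emulate: correlated estimates from the
same study (gender rows are drawn independently), non-normal between-study
effect distributions, within-survey measurement error or recall bias, and
country-level clustering. Passing recovery tests therefore shows the
estimators are calibrated under the model's own assumptions — not that
those assumptions hold in any real survey collection.

`recovery_experiment` runs the full pipeline over replicate datasets
(fixed sub-seeds spawned from one master seed) and reports bias, RMSE and
CI coverage for μ, τ² summaries, and the rejection rates of the moderator
omnibus test (at 0.0125) and the Egger test (at 0.05) — type-I error under
null configurations, power otherwise. Under homogeneity (τ = 0) the REML
estimate piles up at the boundary (≈ half the replicates exactly 0, median
a few percent of the within-study variance) rather than having an exactly
zero median.

## Numerical choices and problem sizes

- Critical value 1.959964 (Φ⁻¹(0.975)) everywhere a 95% interval appears.
- REML tolerance 1e-8, max 200 iterations; brute-force validation uses an
  exhaustive τ² grid at 1e-6 resolution on [0, 1], agreeing to ≤ 1e-5.
- Validation experiment sizes: 50 SE configurations × 10⁵ multinomial
  draws; 100 grid-search comparisons (k ≤ 15); 500 replicates each for
  recovery (k = 40, n = 1000, μ = −0.05, τ = 0.05) and for the null
  calibration of the moderator and Egger tests (default study conditions).
  These sizes hold Monte-Carlo error well below the tolerances they are
  checked against while keeping the whole validation run to ~half a minute.
- The pipeline report is byte-deterministic for identical inputs and
  configuration (sorted JSON keys, no timestamps).

## Known limitations

- Estimates from the same study (gender-stratified rows) are pooled as
  independent; no multilevel or cluster-robust variance is fitted.
- Wald (not Knapp–Hartung) inference is anti-conservative at small k;
  with k in the 5–10 range (frequency/quantity/HED subsets) CIs should be
  read accordingly.
- The marginal-prevalence SE substitution ignores the before/during
  pairing and overstates uncertainty for those estimates.
- The Egger test at small k has low power, and its mixed-effects variant
  re-estimates τ² under the bias model; both choices are recorded in the
  output metadata.
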