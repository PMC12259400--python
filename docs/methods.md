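# Methods

## The causal design

The package implements a repeated cross-section instrumental-variable
design.  One row is one survey respondent with state of residence and
survey year; state-year beverage excise taxes are merged on and used as
instruments for individual drinks per day.  The estimand reported
throughout is the marginally standardised risk ratio per SD of exposure:

    RR = E_C[ Φ(a + β(x̄+s) + δ'C) ] / E_C[ Φ(a + βx̄ + δ'C) ]

with x̄ and s the analysis-sample exposure mean and SD.  The IV assumptions
are the usual three: relevance (checked by the first-stage partial F, with
the conventional F > 10 rule), conditional exchangeability and exclusion
(not testable; probed by sensitivity and falsification analyses).  Because
the instruments shift consumption only for tax-responsive drinkers, the IV
estimate is a complier-type effect, not a population average.

## Generative model of the synthetic cohort

`synthetic_cohort` draws, per study:

* **Taxes** — per state and beverage, a persistent state level plus
  year-specific innovations: `tax = mean + state_effect + year_noise`,
  truncated at 0, with `tax_state_persistence` (default 0.9) of the
  variance in the state effect.  Defaults (means 0.6/1.5/8.4, SDs
  0.5/1.1/4.5 $ per gallon for beer/wine/spirits; cigarette pack tax
  4.4 (2.2) $) match the descriptive moments of the 2003–2012 cohort the
  design emulates.
* **Covariates** — independent marginals matching the same descriptives:
  age ~ Normal(54.5, 14.2²) truncated at ≥ 30; female 54.6%; race
  White/Black/Hispanic/Other 84.2/5.4/5.6/4.8%; six education levels
  (0.1–45.3%); smoking never/current/former 48.6/17.7/33.7%.  Covariate
  independence is a deliberate simplification: it is sufficient for
  validating estimators, whose consistency does not depend on covariate
  correlation, but it means the generator does not reproduce, e.g., the
  real age-smoking gradient.
* **Exposure** — `X = γ'C + π'Z + ε`, truncated below at 0.1 drinks/day so
  every simulated respondent is a current drinker, mirroring the analysis
  restriction.  The truncation (~4–5% of draws) attenuates the linear
  first stage by roughly 4% of each slope; recovery tests therefore use
  3-SE tolerances on the realistic-magnitude preset.
* **Outcome** — latent-index probit `Y = 1[a + βX + δ'C + u > 0]` with
  `(ε, u)` bivariate normal, `corr = rho`.  Endogeneity is generated
  through the correlated error pair rather than an explicit confounder
  variable; for a bivariate-normal confounder the two are equivalent and
  ρ stays directly interpretable.  An optional `instrument_u_corr` knob
  adds a component of the (standardised) beer tax to `u`, creating a
  deliberately invalid instrument for bounds experiments.  The continuous
  latent index is emitted as a truth-only `y_latent` column so linear-model
  oracles have an outcome whose 2SLS estimand is exactly β.
* **Mediators/controls** — BMI (linear in X), dental visits and CHD
  (independent-error probits with positive X effects), calibrated to ~70%
  and ~6% prevalence.
* **Negative-control stratum** — a `negative_fraction` (default 10%) block
  with ages 10–15, β forced to 0, and an intercept offset cancelling the
  age effect so the stratum has non-degenerate outcome prevalence.  This is
  an explicitly synthetic falsification device: a real under-16 population
  would have essentially zero edentulism and nothing could be estimated.

Determinism: one global seed with fixed per-table substream offsets, so tax
tables, cohorts and oracle draws regenerate independently.

Known deviations from real survey data: no survey weights or sampling
strata, no covariate correlations, a thinner right tail of drinking than
observed (the ≥ 5 drinks/day cell is under-represented), and no secular
trends in taxes.  Passing tests therefore demonstrate estimator
correctness under the stated model, not robustness to survey-design
features.

## Presets

* **paperlike** — all moments at the emulated cohort's values, including
  first-stage coefficients (beer −0.017, wine +0.012, spirits −0.003
  drinks/day per $).  β = 0.05 per drink and intercept −5.05 give ~4.3%
  prevalence and a true marginal RR per SD of ≈ 1.0925 (oracle at n = 10⁷).
  ρ = 0.06, derived so the naive-vs-IV divergence matches the magnitude
  such cohorts display (naive latent coefficient ≈ β + 0.8ρ).
* **calibration** — identical structural model with first-stage
  coefficients scaled ×16 (sign pattern and beverage mix preserved) and
  the exposure intercept raised to keep mean drinks/day at 2.0.  Rationale
  (a power analysis done when the experiments were designed): at paperlike
  instrument strength, Var(π'Z) ≈ 4.3·10⁻⁴, so the sampling SD of any
  consistent IV estimator of β at n = 10⁵ is ≈ 0.04 on the latent scale
  once the probit information loss at 4.3% prevalence (factor ≈ 0.21) is
  included — larger than the effects being recovered, and the partial F at
  n ≤ 2·10⁴ falls below the design's own relevance precondition (F > 10).
  Scaling ×16 puts the Monte-Carlo SE of a 50-replicate recovery mean at
  ≈ 0.008 on the RR scale and keeps F > 10 at every simulated size
  (n = 10⁴–10⁵).  The calibration preset is the default for Monte-Carlo
  validation; the paperlike preset is the realistic-magnitude reference.

## Estimators and numerics

* **First stage / 2SLS** — ordinary least squares via normal equations
  with explicit rank checks (collinear columns are named in the error);
  partial F from the restricted-vs-full RSS comparison.  2SLS uses
  heteroscedasticity-robust (HC0) SEs by default — linear-probability
  errors are heteroscedastic by construction — with an optional
  state-cluster sandwich (off by default).
* **Probit engine** — Newton–Raphson with analytic gradient and Hessian,
  log-scale normal CDF throughout (`log_ndtr`), halving line search,
  iteration cap 100.  Separation is detected as a diverging linear
  predictor (|Xb| > 40) and raised with advice to use a larger sample.
* **Joint MLE** — per-observation log-likelihood
  `ln φ((x−w'α)/σ) − ln σ + ln Φ(q·m)` with
  `m = (v'b + (ρ/σ)(x−w'α))/√(1−ρ²)`, `q = 2y−1`, parameterised by
  atanh(ρ) and ln σ for unconstrained optimisation.  Initialisation uses
  the control-function probit (Y on X, C and the first-stage residual),
  which is a smooth reparameterisation of the MLE, so BFGS with the
  analytic gradient (numerically verified in tests) only polishes.
  Covariance is the inverse observed information, obtained by
  central-differencing the analytic gradient.  |ρ̂| > 0.995 sets a boundary
  flag; non-convergence (gradient norm above 10⁻³ after the 200-iteration
  cap and one refinement pass) is an error.  The Wald exogeneity statistic
  is (atanh ρ̂ / SE)² against χ²(1) — the standard-software construction.
* **2SPS** — OLS first stage, probit on (X̂, C).  Its second-stage
  covariance ignores first-stage noise and is flagged; ratio inference
  uses the bootstrap, which re-runs both stages per replicate.  The MLE is
  reported as primary and 2SPS as a concordance check.
* **Standardisation & bootstrap** — percentile CIs (B = 250 by default),
  resampling individuals (state-cluster resampling available; instruments
  vary only at state-year level).  The exposure contrast (x̄, s) is held
  at the original-sample values across replicates so all replicates
  estimate the same ratio; per-SD contrasts within sex strata use the
  stratum's own SD by default (configurable to the pooled SD).  Replicates
  that fail (e.g. a resample drops a rare covariate cell) are counted and
  dropped; > 20% failures is a hard error.  A cheap alternative CI maps
  the Wald CI of β through the standardisation (strictly monotone in β),
  used for calibration experiments and the control-outcome blocks.
* **Imperfect-instrument bounds** — variables are residualised on the
  covariates before forming V(λ) = σ_X Z − λ σ_Z X (equivalent to treating
  C as included instruments).  Under sign concordance and dominance of the
  exposure-error correlation, the V(1)-2SLS errs on the assumed direction
  side and the Z-2SLS on the side `direction × sign(corr(Z,X))`; when the
  two sides differ the interval is two-sided, otherwise one side is
  unbounded.  The CI is the union of the bounding estimators' one-sided
  95% limits — conservative, and the simplest defensible choice.  Bounds
  are computed per instrument (beer's negative first stage gives two-sided
  intervals under positive confounding; wine's positive one gives an upper
  bound).  A first-stage F floor (default 4) on the bounding instruments
  raises an "uninformative bound" error.  With multiple taxes, a bound
  uses one named instrument; the remaining taxes are simply unused.

## Data handling

Loaders consume delimited text with a header and an optional
canonical→source column map; every rejected row is counted per reason, and
`n_input = n_retained + Σ drops` is an invariant.  Hard errors: missing
mandatory columns, duplicate (state, year) tax rows, individuals whose
(state, year) is absent from the tax table.  Taxes can be deflated to a
base year from a user-supplied CPI series.  Linkage applies the
eligibility filters (age ≥ 30, positive exposure, complete cases) and
reference-codes categoricals against the largest cells (male, White,
college graduate, never smoker) — a choice that moves intercepts only.
Education is treated as nominal, the conservative reading of an ordinal
scale.  Empty categorical cells (all-zero dummies, common in small strata)
are dropped from the design and recorded in the dataset metadata.  The
exposure SD for the "per SD" contrast is computed on the analysis sample
after all filters.  Drinks-per-day categories follow the half-open reading
(0,2], (2,5), [5,∞) — the only assignment consistent with the printed
category labels.  Survey weights are unsupported (documented limitation).

## Monte-Carlo validation suite

`tests/test_acceptance.py` runs six experiments (sizes chosen with the
power analysis above so each completes in minutes on one CPU):

1. recovery — 50 studies of n = 10⁵; the mean MLE risk ratio must sit
   within 0.02 of the oracle;
2. discrimination — 100 studies at n = 5·10⁴ with β = 0, ρ = 0.3; the
   naive probit must reject the null in ≥ 80% while the IV bootstrap CI
   covers 1 at its nominal rate;
3. exogeneity-test size — 500 null studies at n = 10⁴; rejection rate in
   [3%, 7%] at α = 0.05;
4. exact identities — partial F = t² (single instrument), self-instrumented
   2SLS = OLS, ρ-constrained MLE = probit + OLS, V(0)-2SLS = Z-2SLS;
5. bounds robustness — 200 studies with a deliberately invalid instrument
   (corr(Z,u) = 0.05, corr(ε,u) = 0.3, concordant signs, continuous latent
   outcome); the bound CI must cover β in ≥ 95%;
6. bootstrap coverage — 200 studies at n = 2·10⁴ with B = 100 (scaled down
   from the default 250); CI coverage of the oracle RR in [90%, 98%].

## Limitations

Linear first stage and single endogenous regressor only; no nonlinear
dose–response (a structural limit of this IV design); no survey weights;
cluster-robust covariance available for the linear fits but not the MLE;
bounds theory is linear, hence the switch to the linear probability model
there; the negative-control stratum is a synthetic device, not a model of
a real under-16 survey population.
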