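# "calibration" preset: same structural model as "paperlike" but with the
# first-stage coefficients scaled x16 (sign pattern and beverage mix
# preserved) so the instrument-relevance precondition (partial F > 10)
# holds at Monte-Carlo sample sizes of 10k-100k and the Monte-Carlo SE of
# recovery/coverage experiments sits well below their tolerances.  The
# exposure intercept is raised to keep mean drinks/day at ~2.0 despite the
# larger tax contribution.  See docs/methods.md for the power analysis.
n_states: 51
n_years: 7
n_individuals: 100000
tax_means: [0.6, 1.5, 8.4]
tax_sds: [0.5, 1.1, 4.5]
tax_state_persistence: 0.9
cigarette_tax_mean: 4.4
cigarette_tax_sd: 2.2
pi: [-0.272, 0.192, -0.048]
gamma:
  age: -0.004
  female: -0.3
  smoke_current: 0.3
  smoke_former: 0.1
x_intercept: 2.59
sigma_eps: 1.05
beta: 0.05
delta:
  age: 0.045
  female: -0.05
  race_black: 0.3
  race_hispanic: 0.1
  race_other: 0.1
  edu_no_certificate: 1.0
  edu_elementary: 0.9
  edu_some_high_school: 0.7
  edu_high_school_graduate: 0.4
  edu_some_college: 0.2
  smoke_current: 0.6
  smoke_former: 0.25
intercept: -5.05
rho: 0.06
instrument_u_corr: 0.0
mediator_effects:
  bmi: 0.4
  dental_visit: 0.15
  chd: 0.08
negative_fraction: 0.1
seed: 20240502
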