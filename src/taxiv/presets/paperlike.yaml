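# "paperlike" preset: descriptive moments of the pooled 2003-2012 adult
# cohort this design emulates.  Tax order is (beer, wine, spirits), in
# 2012 US$ per gallon.  First-stage coefficients keep the observed sign
# pattern (beer/spirits negative, wine positive) and printed magnitudes;
# beta and the latent intercept are calibrated so the marginally
# standardised risk ratio per SD is ~1.13 at ~4.3% outcome prevalence;
# rho = 0.06 reproduces the observed naive-vs-IV divergence magnitude.
n_states: 51
n_years: 7
n_individuals: 100000
tax_means: [0.6, 1.5, 8.4]
tax_sds: [0.5, 1.1, 4.5]
tax_state_persistence: 0.9
cigarette_tax_mean: 4.4
cigarette_tax_sd: 2.2
pi: [-0.017, 0.012, -0.003]
gamma:
  age: -0.004
  female: -0.3
  smoke_current: 0.3
  smoke_former: 0.1
x_intercept: 2.31
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
seed: 20240501
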