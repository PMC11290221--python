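# Scenario catalogue for the piecewise-exponential simulation study.
#
# Hazard for patient i:
#   lambda_i(t) = lambda0 * exp{ (b1*I(t<eps) + b2*I(t>=eps)) * arm
#                                + gamma*(z1 + z2 + z3) }
# expressed below on the hazard-ratio scale: hr1 = exp(b1), hr2 = exp(b2),
# cov_hr = exp(gamma).  epsilon in months.  Censoring is Uniform[20, 40]
# months (uniform accrual over 20 months, minimum follow-up 20 months).
scenarios:
  "null":        {lambda0: 2.00, epsilon: 0.00, hr1: 1.00, hr2: 1.00, cov_hr: 0.20}
  strong_null_A: {lambda0: 0.60, epsilon: 1.00, hr1: 16.0, hr2: 0.80, cov_hr: 0.20}
  strong_null_B: {lambda0: 0.04, epsilon: 1.00, hr1: 16.0, hr2: 0.70, cov_hr: 0.90}
  PH:            {lambda0: 2.00, epsilon: 0.00, hr1: 0.70, hr2: 0.70, cov_hr: 0.20}
  delayed:       {lambda0: 2.00, epsilon: 5.00, hr1: 1.00, hr2: 0.40, cov_hr: 0.20}
  crossing:      {lambda0: 2.00, epsilon: 5.00, hr1: 1.25, hr2: 0.40, cov_hr: 0.20}
  diminishing:   {lambda0: 2.00, epsilon: 5.00, hr1: 0.40, hr2: 0.95, cov_hr: 0.20}

# Covariate distribution (binary prognostic factors, i.i.d. per patient).
covariate_prevalence: [0.6666666666666666, 0.6666666666666666, 0.3333333333333333]

# Administrative censoring window (months).
censoring_window: [20.0, 40.0]

# Reduced-replication profiles for the simulation harness.
profiles:
  smoke: {reps_null: 200,   reps_alt: 200,  rerand_m: 200}
  desk:  {reps_null: 2000,  reps_alt: 1000, rerand_m: 500}
  paper: {reps_null: 10000, reps_alt: 5000, rerand_m: 1000}
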