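# Worked-example run configuration: toxicity-only repeated-measures design.
# Every value here is also the library default; the file exists so runs are
# explicit and auditable.

weight_matrix:
  toxmax: 2.5
  types:
    - {name: renal,         weights: [0, 0.5, 0.75, 1, 1.5], dlt_min_grade: 3}
    - {name: neurological,  weights: [0, 0.5, 0.75, 1, 1.5], dlt_min_grade: 3}
    - {name: hematological, weights: [0, 0, 0, 0.5, 1],      dlt_min_grade: 4}

design:
  doses: [1, 2, 3, 4, 5, 6]
  trial_size: 36
  cohort_size: 3
  max_cycle: 5
  start_dose: 1
  tox_target: 0.28

priors:
  beta_dose:  {family: normal, mean: 0, var: 1000}
  beta_cycle: {family: normal, mean: 0, var: 1000}
  s2_gamma:   {family: invgamma, shape: 0.001, scale: 0.001}
  s2_epsilon: {family: invgamma, shape: 0.001, scale: 0.001}

mcmc: {iterations: 2000, burnin: 500, thin: 1, chains: 1, seed: 0}

# proportional-odds toxicity generator for `rmdose simulate`
po_model:
  intercepts: [2, 3, 4.2, 5.7]
  dose_coefs: [-0.2, -0.4, -0.7]
  cycle_coef: 0
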