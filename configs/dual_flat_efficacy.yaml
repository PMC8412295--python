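# Dual-endpoint (toxicity + efficacy) simulation: flat dose-efficacy scenario.
# Mean efficacy 0.5 at every dose, so the design should settle on the lowest
# safe doses.

design:
  doses: [1, 2, 3, 4, 5, 6]
  trial_size: 36
  cohort_size: 3
  max_cycle: 6
  start_dose: 1
  tox_target: 0.23
  c1: 0.23
  c2: 0.23
  p1: 0.1
  p2: 0.1
  ps1: 0.1
  delta: 0.1        # stage-3 proximity threshold (tuning parameter)
  stage1_fraction: 0.5

po_model:
  intercepts: [1.9, 2.3, 2.6, 3.1]
  dose_coefs: [-0.3, -0.2, -0.25]
  cycle_coef: 0

efficacy:
  mean_eff: [0.5, 0.5, 0.5, 0.5, 0.5, 0.5]
  sd_eff: 0.2

mcmc: {iterations: 1000, burnin: 400, thin: 1, chains: 1, seed: 0}
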