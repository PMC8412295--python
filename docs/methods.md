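# Methods

This note records the models implemented in `rmdose`, the numerical choices
behind the sampler and the trial engine, what the simulation scenarios do
and do not emulate, and the places where the design was genuinely open.

## Toxicity scoring

The normalized total toxicity profile (nTTP) maps the per-type maximum
grades of one patient-cycle to
`sqrt(sum_l w[l, G_l]^2) / toxmax`. The Euclidean-norm form is deliberate:
with the default three-type weight matrix (maximal weights 1.5, 1.5, 1.0)
the sum of squared weights can reach 5.5, so only the root form is bounded
by the normalization constant 2.5 and keeps the score inside [0, 1]. The
score is zero iff all grades are zero, monotone in every grade (enforced by
the weight-matrix invariant that weights are non-decreasing within type),
and any DLT-bearing profile scores at least the cheapest single-DLT profile
(0.4 under the defaults).

Grades are actual CTCAE grades 0–4. The DLT rule is per-type configurable
(`dlt_min_grade`), defaulting to grade ≥ 3 for renal/neurological and grade
4 for hematological toxicity.

## Scenario generation

Simulation scenarios are 4-D arrays of grade probabilities indexed (dose,
cycle, type, grade). The parametric path builds them from a cumulative-logit
(proportional-odds) model `logit P(G <= j) = lambda_j + zeta_l*dose +
psi*cycle` with strictly increasing intercepts; grade 4 takes the
complement `1 - c_3`. Dose enters as the integer level 1..K and cycle as
1..J — no unit rescaling. A user-supplied array bypasses the model entirely
(the non-parametric path for historical data).

Toxicity types are sampled independently, and the analytic scenario
summaries assume the same independence: the cycle-1 DLT probability is one
minus the product of per-type sub-DLT masses, and the mean nTTP is an exact
expectation by enumeration over all 5^L grade combinations (125 for three
types). The enumeration is cross-checked against Monte-Carlo sampling in
the tests.

Efficacy outcomes are beta draws matched by moments to a per-dose mean and
a common SD; validity requires `sd^2 < mean*(1-mean)`.

What the generator does **not** emulate: correlated toxicity types,
within-patient serial correlation of grades beyond the dose/cycle trend,
time-varying dose, accrual variation (cohorts are exactly one cycle apart),
or missingness other than post-DLT dropout. Passing simulation tests
therefore says nothing about robustness to those features in real data.

## Posterior computation

Both models are sampled with a bespoke conjugate Gibbs scheme (no external
MCMC engine):

* `(beta0, beta1, beta2)` is drawn as one trivariate Gaussian block from its
  full conditional, truncated to `beta1 > 0` by rejection (up to 64 draws),
  with a scalar truncated-normal fallback afterwards. The block update
  matters: on small collinear designs (e.g. nine observations on two dose
  levels) scalar updates of the intercept and dose effect mix an order of
  magnitude worse.
* Random intercepts `gamma_i` have independent Gaussian conditionals
  (vectorized); variances are inverse-gamma conditionals.
* The joint model adds a trivariate block for `(alpha0, alpha1, alpha2)`,
  a Gaussian conditional for the association loading `nu`, and an
  inverse-gamma conditional for the efficacy error variance. All remain
  conjugate given `gamma`.

Defaults mirror the vague worked-example priors: N(0, 1000) on every fixed
effect and on `nu`, IG(0.001, 0.001) on all variances; 2000 iterations with
500 burn-in, thin 1, one chain, for interactive fits. Initialization is
deterministic (fixed effects 0, `beta1` 0.01, variances 1, `gamma` 0) so a
seed fully determines a run. Multi-chain runs spawn independent substreams
from the seed.

Two consequences of the positivity constraint are worth knowing. First,
`beta1`'s posterior mean sits slightly above the least-squares estimate
(≈ +0.02 on the example trial dataset), so posterior dose means
extrapolated far beyond the tried range drift upward relative to a
plain-least-squares extrapolation; at the tried doses the effect is within
Monte-Carlo noise. Second, with data on a single dose level the dose effect
is identified only through its prior — this is why the run-in rule, not the
model, governs escalation until two dose levels have data.

Cycle coding differs by design. The toxicity-only model codes cycle as
`t = j`, matching a per-cycle trend. The dual-endpoint design codes cycle 1
as `t = 0` and all later cycles as `t = 1`, so the first-cycle safety
condition evaluates the population mean at `t = 0` and a single aggregate
late-cycle mean at `t = 1`. Efficacy is modeled on its raw (0,1) scale with
Gaussian error, as the linear submodel specifies; no transform.

## Trial engine

Escalation risk is the posterior expectation of the absolute loss
`|cycle-1 mean at dose x - target|` (the expectation of the loss over
draws, not the loss of the posterior mean; the latter is available as a
cross-check toggle and ranks identically on unimodal posteriors). Ties
break toward the lower dose everywhere, and no decision may exceed the
highest tried dose plus one.

The 3+3 run-in (toxicity-only design) uses cycle-1 DLTs at the current
dose: 0/3 escalate, 1/3 expand, ≥ 2/3 or ≥ 2/6 de-escalate (terminate at
the lowest dose), ≤ 1/6 escalate. In the dual-endpoint design the same
rule picks doses during the run-in, but termination is governed by the
posterior safety conditions instead — a de-escalation below the lowest dose
holds at the lowest dose, and the trial stops only when no dose satisfies
the stage-appropriate allowability condition. This keeps early stopping
semantics uniform across all three stages (empty allowable set), which is
how the dual design describes its stopping rule.

Stage boundaries are sample-size based: stage 1 until `N * stage1_fraction`
(default half), stage 2 until N, stage 3 at N. Stage 1 allowability uses
the cycle-1 condition only, with its own cutoff `ps1`. Stage 2 refits the
joint model at every cohort (the refit cadence is unstated in the design;
per-cohort is the most adaptive choice), updates the allowable set with
both conditions, and randomizes the next cohort with probabilities
proportional to `exp(predicted efficacy)` over the allowable doses within
the no-skip cap. Stage 3 takes the allowable dose maximizing predicted
efficacy, forms the set H of allowable doses within `delta` of it, and
recommends `min(H)`.

`delta` has no canonical value; it trades selectivity against safety on the
efficacy scale. The shipped configurations use 0.1 (the order of one
efficacy SD) and treat it as a tuning parameter to be calibrated by
simulation, like the probability cutoffs.

In simulated trials the final MTD (toxicity-only design) is capped at the
highest dose actually tried: recommending an untested dose as the MTD has
no clinical meaning even though interim decisions may step one level above.

## Simulation

Cohorts enroll one cycle apart; at each decision, cohort b has contributed
`min(current - b, max_cycle)` cycles (fewer after a DLT dropout), and
exactly those rows feed the refit. Efficacy is observed once a patient's
first cycle completes, i.e. for every previously enrolled patient. Per-trial
seeds are spawned from the master seed with a counter-based scheme, so any
single trial can be reproduced in isolation. Simulated-trial refits default
to 1000 iterations / 400 burn-in — decisions are refit at every cohort, so
shorter chains than an interactive one-off fit are appropriate; the
operating characteristics reported by the acceptance script use 100
simulated trials of 36 patients.

Operating characteristics report per-dose allocation (fraction of patients)
and recommendation (fraction of trials) percentages plus the early-stop
rate; recommendation mass and early stops sum to one by construction. The
scenario-truth block attached to every summary comes from the analytic
enumeration, not from the sampled trials.

Under the flat-efficacy evaluation scenario (all mean efficacies 0.5,
efficacy SD 0.2, bounds and target 0.23, all probability cutoffs 0.1,
`delta` 0.1) the design concentrates its recommendations on the lowest one
to two doses, as it should: with no efficacy gradient the lowest safe dose
is optimal. The exact split between dose 1 and dose 2 is sensitive to the
efficacy SD and `delta` — larger efficacy noise makes the fitted efficacy
curve tilt by more than `delta` more often, excluding dose 1 from H more
frequently — so those two values are part of any reported operating
characteristic.

## Known limitations

* Single random intercept (compound symmetry); no richer covariance
  structures or serial correlation.
* Efficacy error is Gaussian on (0,1); no boundary-respecting likelihood.
* No intra-patient dose adjustment; dose is fixed at enrollment.
* Convergence monitoring is limited to multi-seed agreement checks in the
  tests; no formal diagnostics ship with the sampler.
* The independence-across-types assumption is untestable from the scenario
  arrays alone and is inherited by every analytic summary.
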