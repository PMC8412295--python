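# rmdose

Repeated-measures dose-finding designs for phase I oncology trials, built
around a quasi-continuous toxicity score observed over multiple treatment
cycles, with an optional continuous early-efficacy endpoint.

Classical phase I designs reduce each patient to a single binary
dose-limiting-toxicity (DLT) indicator from cycle 1, which wastes most of
the adverse-event record of targeted agents and immunotherapies — drugs
whose toxicity is often moderate, chronic, and cumulative, and whose
efficacy need not increase with dose. `rmdose` implements the alternative:
score every cycle of every patient, model the longitudinal scores, and (when
an early efficacy readout exists) pick the lowest dose among the safe,
near-optimally efficacious ones.

The package is aimed at trial statisticians: it recommends the next cohort's
dose from accumulated trial data (interactive conduct) and evaluates design
operating characteristics by simulation (design stage).

## The model

**Toxicity score.** For patient *i* in a cycle, let *G<sub>il</sub>* be the
maximum observed grade of toxicity type *l* (renal, neurological,
hematological in the worked example) and *w<sub>lh</sub>* the
clinician-elicited severity weight of type *l* at grade *h*. The normalized
total toxicity profile is

> nTTP<sub>i</sub> = √( Σ<sub>l</sub> w<sup>2</sup><sub>l,G<sub>il</sub></sub> ) / v ∈ [0, 1],

with normalization constant *v* (2.5 in the example). DLTs remain defined
per type (grade ≥ 3 renal/neurological, grade 4 hematological) and trigger
patient dropout.

**Longitudinal model.** nTTP scores y<sub>ij</sub> at dose x<sub>i</sub> and
cycle t<sub>j</sub> follow a random-intercept linear mixed model

> y<sub>ij</sub> = β₀ + β₁x<sub>i</sub> + β₂t<sub>j</sub> + γ<sub>i</sub> + ε<sub>ij</sub>,  β₁ > 0,

fit by a conjugate Gibbs sampler with vague priors. Escalation minimizes the
posterior Bayesian risk E[ |β₀ + β₁x + β₂t₁ − π₁| | data ] against a target
cycle-1 score π₁, never skipping an untested dose. A conventional 3+3 run-in
applies until two dose levels have data.

**Dual endpoint.** A per-patient efficacy outcome E<sub>i</sub> ∈ (0,1) adds
the linked submodel E<sub>i</sub> = α₀ + α₁x<sub>i</sub> + α₂x²<sub>i</sub> +
νγ<sub>i</sub> + e<sub>i</sub> (shared random intercept, compound-symmetry
association). The trial runs in three stages: toxicity-driven escalation to
N/2; adaptive randomization of later cohorts among allowable doses — those
with P(cycle-1 mean < c₁ | data) > p₁ and P(late-cycle mean < c₂ | data) >
p₂ — with probabilities ∝ exp(predicted efficacy); and a final selection of
the lowest dose whose predicted efficacy is within δ of the best allowable
dose. An empty allowable set terminates the trial.

## Worked example

Score one patient-cycle (grade 1 renal, grade 2 neurological, no
hematological toxicity) under the default weight matrix:

```console
$ rmdose score 1,2,0
nTTP: 0.36056
DLT: no
```

The score is √(0.5² + 0.75²)/2.5: two moderate events register as a third of
the maximal toxicity burden, where a DLT-based analysis would record
nothing.

Recommend the next cohort's dose from the built-in two-cohort example trial
(6 patients at dose 1 over two cycles, 3 at dose 2; target π₁ = 0.28):

```console
$ rmdose fixture patdata --outdir .
$ rmdose next-dose --data patdata.csv --seed 1
Model: RMD with longitudinal toxicity
Doses (skeleton): 1  2  3  4  5  6
The maximum sample size is: 36
The current enrolled number of patients are: 6
Posterior estimates (mean) of toxicity:
        Dose 1  Dose 2  Dose 3  Dose 4  Dose 5  Dose 6
toxpf1   0.064   0.238   0.413   0.588   0.763   0.937
toxpf2   0.132   0.306   0.481   0.656   0.830   1.005
toxpf3   0.199   0.374   0.549   0.723   0.898   1.073
toxpf4   0.267   0.442   0.617   0.791   0.966   1.141
toxpf5   0.335   0.510   0.684   0.859   1.034   1.209
Next recommended dose: 2
```

Each `toxpf` row is the posterior mean nTTP per dose for one cycle. Dose 2's
cycle-1 mean (0.238) is closest to the 0.28 target, so dose 2 is assigned to
the next cohort; dose 3 is the highest level the no-skip rule would have
allowed.

Simulate the toxicity-only design under a proportional-odds scenario and
report operating characteristics (`$sc` is the analytic scenario truth —
mean nTTP per cycle and dose, plus the cycle-1 DLT probability):

```bash
rmdose simulate --config configs/example.yaml --n-trials 100 --seed 1
rmdose simulate-dual --config configs/dual_flat_efficacy.yaml --n-trials 100 --seed 1
```

The library mirrors every subcommand (`rmdose.fit_tox_lmm`,
`rmdose.recommend_dose_tox`, `rmdose.sim_rmd_eff`, ...) for programmatic
use; see `docs/methods.md` for the modeling details and design choices.

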