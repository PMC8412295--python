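"""Whole-trial simulation and operating characteristics.

Trials enroll cohorts of size m one treatment cycle apart: when cohort c is
about to enroll, an earlier cohort b has completed min(c - b, max_cycle)
cycles (fewer if a patient dropped out after a DLT), and exactly those
observed patient-cycles feed the dose decision.  Patients keep their
assigned dose across cycles and drop out after the first cycle with a DLT.
In the dual-endpoint design each patient additionally contributes one
efficacy outcome, observed once their first cycle is complete.

Operating characteristics aggregate many independently seeded trials into
per-dose allocation percentages (fraction of patients treated) and
recommendation percentages (fraction of trials selecting each dose), plus
the early-termination rate, and carry the analytic scenario truth (mean
nTTP per dose and cycle, cycle-1 DLT probability, mean efficacy) for
reference.  Per-trial seeds are spawned from a master seed so individual
trials are reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes import McmcOptions, PriorSpec
from .design import (
    DesignConfig,
    DualDesignConfig,
    RecommendationResult,
    recommend_dose_tox,
    run_trial_dual,
)
from .errors import ValidationError
from .scenarios import (
    EffScenario,
    ToxProbArray,
    sample_efficacy,
    sample_patient_cycle,
    scenario_truth,
)
from .toxicity import WeightMatrix

#: MCMC sizes used inside simulated trials (shorter chains than a one-off
#: interactive fit; decisions are refit at every cohort).
SIM_MCMC = McmcOptions(iterations=1000, burnin=400, thin=1, chains=1, seed=0)


@dataclass(frozen=True)
class TrialRecord:
    """Audit trail of one simulated trial."""

    tox: pd.DataFrame  # columns uniqueID, cohort, subj, dose, cycle, nTTP, DLT
    eff: pd.DataFrame | None
    decisions: tuple[RecommendationResult, ...]
    recommendation: int | None
    stopped_early: bool

    @property
    def n_patients(self) -> int:
        return self.tox["uniqueID"].nunique() if len(self.tox) else 0

    def allocation_counts(self, doses: tuple[int, ...]) -> dict[int, int]:
        per_patient = self.tox.drop_duplicates("uniqueID") if len(self.tox) else self.tox
        counts = dict.fromkeys(doses, 0)
        for d in per_patient["dose"] if len(per_patient) else []:
            counts[int(d)] += 1
        return counts


@dataclass(frozen=True)
class OperatingCharacteristics:
    allocation_pct: dict[int, float]
    recommendation_pct: dict[int, float]
    early_stop_pct: float
    n_trials: int
    truth: pd.DataFrame

    def op_table(self) -> pd.DataFrame:
        doses = sorted(self.allocation_pct)
        return pd.DataFrame(
            {
                f"Dose {d}": [self.allocation_pct[d], self.recommendation_pct[d]]
                for d in doses
            },
            index=["Allocation %", "Recommendation %"],
        )

    def format_report(self, trial_size: int) -> str:
        lines = [
            f"Operating characteristics based on {self.n_trials} simulations",
            f"Sample size {trial_size}",
            "",
            "$op.table",
            self.op_table().round(3).to_string(),
            "",
            "$sc",
            self.truth.round(4).to_string(),
        ]
        if self.early_stop_pct > 0:
            lines.append("")
            lines.append(f"Early termination %: {self.early_stop_pct:.3f}")
        return "\n".join(lines)


def _check_dims(scenario: ToxProbArray, wm: WeightMatrix, cfg: DesignConfig) -> None:
    if scenario.n_doses < len(cfg.doses):
        raise ValidationError("scenario covers fewer doses than the design")
    if scenario.n_cycles < cfg.max_cycle:
        raise ValidationError("scenario covers fewer cycles than max_cycle")
    if scenario.n_types != wm.n_types:
        raise ValidationError("scenario and weight matrix disagree on toxicity types")


def _enroll_cohort(
    scenario: ToxProbArray,
    wm: WeightMatrix,
    cohort: int,
    dose: int,
    size: int,
    max_cycle: int,
    rng: np.random.Generator,
) -> list[dict]:
    """Draw full multi-cycle outcomes for one cohort (dropout after a DLT cycle)."""
    rows = []
    for subj in range(1, size + 1):
        pid = f"cohort{cohort}subj{subj}"
        for cycle in range(1, max_cycle + 1):
            _, nttp, dlt = sample_patient_cycle(scenario, dose, cycle, wm, rng)
            rows.append(
                {
                    "uniqueID": pid,
                    "cohort": cohort,
                    "subj": subj,
                    "dose": dose,
                    "cycle": cycle,
                    "nTTP": nttp,
                    "DLT": int(dlt),
                }
            )
            if dlt:
                break
    return rows


def _visible(tox: pd.DataFrame, current_cohort: int) -> pd.DataFrame:
    """Rows observable when cohort ``current_cohort`` is about to enroll."""
    if len(tox) == 0:
        return tox
    completed = current_cohort - tox["cohort"]
    return tox[tox["cycle"] <= completed]


def _decision_mcmc(base: McmcOptions, rng: np.random.Generator) -> McmcOptions:
    seed = int(rng.integers(2**31))
    return McmcOptions(base.iterations, base.burnin, base.thin, base.chains, seed)


def simulate_trial_tox(
    scenario: ToxProbArray,
    wm: WeightMatrix,
    cfg: DesignConfig,
    priors: PriorSpec = PriorSpec(),
    mcmc: McmcOptions = SIM_MCMC,
    rng: np.random.Generator | None = None,
) -> TrialRecord:
    """Simulate one toxicity-only trial; the final MTD uses the complete data."""
    _check_dims(scenario, wm, cfg)
    rng = rng if rng is not None else np.random.default_rng(mcmc.seed)
    n_cohorts = -(-cfg.trial_size // cfg.cohort_size)
    rows: list[dict] = []
    decisions: list[RecommendationResult] = []
    stopped = False
    for c in range(1, n_cohorts + 1):
        tox = pd.DataFrame(rows, columns=["uniqueID", "cohort", "subj", "dose", "cycle", "nTTP", "DLT"])
        rec = recommend_dose_tox(_visible(tox, c), cfg, priors, _decision_mcmc(mcmc, rng))
        decisions.append(rec)
        if rec.terminated:
            stopped = True
            break
        size = min(cfg.cohort_size, cfg.trial_size - (c - 1) * cfg.cohort_size)
        rows.extend(_enroll_cohort(scenario, wm, c, rec.next_dose, size, cfg.max_cycle, rng))
    tox = pd.DataFrame(rows, columns=["uniqueID", "cohort", "subj", "dose", "cycle", "nTTP", "DLT"])
    if stopped:
        recommendation = None
    else:
        final = recommend_dose_tox(tox, cfg, priors, _decision_mcmc(mcmc, rng), final=True)
        decisions.append(final)
        recommendation = final.next_dose
    return TrialRecord(
        tox=tox, eff=None, decisions=tuple(decisions),
        recommendation=recommendation, stopped_early=stopped,
    )


def _aggregate(
    records: list[TrialRecord], cfg: DesignConfig, truth: pd.DataFrame
) -> OperatingCharacteristics:
    n_trials = len(records)
    alloc = dict.fromkeys(cfg.doses, 0)
    recs = dict.fromkeys(cfg.doses, 0)
    stops = 0
    total_patients = 0
    for r in records:
        for d, c in r.allocation_counts(cfg.doses).items():
            alloc[d] += c
            total_patients += c
        if r.recommendation is None:
            stops += 1
        else:
            recs[r.recommendation] += 1
    return OperatingCharacteristics(
        allocation_pct={d: alloc[d] / total_patients for d in cfg.doses},
        recommendation_pct={d: recs[d] / n_trials for d in cfg.doses},
        early_stop_pct=stops / n_trials,
        n_trials=n_trials,
        truth=truth,
    )


def sim_rmd(
    scenario: ToxProbArray,
    wm: WeightMatrix,
    cfg: DesignConfig,
    priors: PriorSpec = PriorSpec(),
    mcmc: McmcOptions = SIM_MCMC,
    n_trials: int = 100,
    seed: int = 0,
) -> OperatingCharacteristics:
    """Operating characteristics of the toxicity-only design over seeded trials."""
    if n_trials < 1:
        raise ValidationError("n_trials must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(n_trials)
    records = [
        simulate_trial_tox(scenario, wm, cfg, priors, mcmc, np.random.default_rng(s))
        for s in streams
    ]
    return _aggregate(records, cfg, scenario_truth(scenario, wm))


def simulate_trial_dual(
    scenario: ToxProbArray,
    eff_scenario: EffScenario,
    wm: WeightMatrix,
    cfg: DualDesignConfig,
    priors: PriorSpec = PriorSpec(),
    mcmc: McmcOptions = SIM_MCMC,
    rng: np.random.Generator | None = None,
) -> TrialRecord:
    """Simulate one three-stage dual-endpoint trial."""
    _check_dims(scenario, wm, cfg)
    if eff_scenario.n_doses < len(cfg.doses):
        raise ValidationError("efficacy scenario covers fewer doses than the design")
    rng = rng if rng is not None else np.random.default_rng(mcmc.seed)
    n_cohorts = -(-cfg.trial_size // cfg.cohort_size)
    rows: list[dict] = []
    eff_rows: list[dict] = []
    decisions: list[RecommendationResult] = []
    stopped = False
    cols = ["uniqueID", "cohort", "subj", "dose", "cycle", "nTTP", "DLT"]
    for c in range(1, n_cohorts + 1):
        tox = pd.DataFrame(rows, columns=cols)
        vis = _visible(tox, c)
        vis_ids = set(vis["uniqueID"]) if len(vis) else set()
        eff = pd.DataFrame(
            [r for r in eff_rows if r["subID"] in vis_ids],
            columns=["subID", "dose", "Efficacy"],
        )
        rec = run_trial_dual(vis, eff, cfg, priors, _decision_mcmc(mcmc, rng), rng=rng)
        decisions.append(rec)
        if rec.terminated:
            stopped = True
            break
        size = min(cfg.cohort_size, cfg.trial_size - (c - 1) * cfg.cohort_size)
        new_rows = _enroll_cohort(scenario, wm, c, rec.next_dose, size, cfg.max_cycle, rng)
        rows.extend(new_rows)
        for pid in dict.fromkeys(r["uniqueID"] for r in new_rows):
            eff_rows.append(
                {
                    "subID": pid,
                    "dose": rec.next_dose,
                    "Efficacy": sample_efficacy(eff_scenario, rec.next_dose, rng),
                }
            )
    tox = pd.DataFrame(rows, columns=cols)
    eff = pd.DataFrame(eff_rows, columns=["subID", "dose", "Efficacy"])
    if stopped:
        recommendation = None
    else:
        final = run_trial_dual(tox, eff, cfg, priors, _decision_mcmc(mcmc, rng), rng=rng)
        decisions.append(final)
        recommendation = final.next_dose
    return TrialRecord(
        tox=tox, eff=eff, decisions=tuple(decisions),
        recommendation=recommendation, stopped_early=stopped,
    )


def sim_rmd_eff(
    scenario: ToxProbArray,
    eff_scenario: EffScenario,
    wm: WeightMatrix,
    cfg: DualDesignConfig,
    priors: PriorSpec = PriorSpec(),
    mcmc: McmcOptions = SIM_MCMC,
    n_trials: int = 100,
    seed: int = 0,
) -> OperatingCharacteristics:
    """Operating characteristics of the three-stage dual-endpoint design."""
    if n_trials < 1:
        raise ValidationError("n_trials must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(n_trials)
    records = [
        simulate_trial_dual(
            scenario, eff_scenario, wm, cfg, priors, mcmc, np.random.default_rng(s)
        )
        for s in streams
    ]
    truth = scenario_truth(scenario, wm, eff_means=eff_scenario.mean_eff[: scenario.n_doses])
    return _aggregate(records, cfg, truth)
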