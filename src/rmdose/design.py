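"""Dose-decision engine: Bayesian-risk escalation and the three-stage dual design.

Toxicity-only design.  Enrollment starts with a conventional 3+3 run-in;
once data exist on at least two dose levels the decision switches to the
model: fit the longitudinal nTTP mixed model and allocate the dose whose
posterior expected absolute loss

    E[ |mean cycle-1 nTTP at dose x  -  target| | data ]

is smallest, subject to never skipping an untested dose (candidates are
capped at one level above the highest dose already tried) and breaking
ties toward the lower dose.

Dual-endpoint design (three stages, maximum sample size N):

* Stage 1 (first half of enrollment): toxicity-driven escalation as above,
  restricted to stage-1 allowable doses — those with posterior probability
  above ``ps1`` that the cycle-1 mean nTTP is below the bound ``c1``.
* Stage 2: refit the joint toxicity-efficacy model after each cohort,
  update the allowable set A (cycle-1 mean below c1 with probability > p1
  AND late-cycle mean below c2 with probability > p2), then randomize the
  next cohort among allowable doses with probability proportional to
  exp(predicted efficacy).
* Stage 3 (trial complete): among allowable doses, find the predicted-
  efficacy maximizer l, collect the near-optimal set
  H = {h in A : |predEff(h) - predEff(l)| <= delta}, and recommend the
  lowest (safest) dose in H.

An empty allowable set at any stage terminates the trial early.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .bayes import (
    JointPosterior,
    McmcOptions,
    PosteriorToxSurface,
    PriorSpec,
    ToxPosterior,
    fit_joint_model,
    fit_tox_lmm,
    posterior_tox_surface,
    predicted_efficacy,
)
from .errors import ValidationError

RiskMethod = Literal["expected_loss", "posterior_mean"]


@dataclass(frozen=True)
class DesignConfig:
    """Toxicity-only design parameters."""

    doses: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    trial_size: int = 36
    cohort_size: int = 3
    max_cycle: int = 5
    start_dose: int = 1
    tox_target: float = 0.28

    def __post_init__(self) -> None:
        object.__setattr__(self, "doses", tuple(int(d) for d in self.doses))
        if not self.doses or list(self.doses) != sorted(set(self.doses)):
            raise ValidationError("doses must be a non-empty increasing sequence")
        if not 0 < self.cohort_size <= self.trial_size:
            raise ValidationError("need 0 < cohort_size <= trial_size")
        if self.start_dose not in self.doses:
            raise ValidationError("start_dose must be one of the doses")
        if not 0.0 < self.tox_target < 1.0:
            raise ValidationError("tox_target must be in (0,1)")
        if self.max_cycle < 1:
            raise ValidationError("max_cycle must be >= 1")


@dataclass(frozen=True)
class DualDesignConfig(DesignConfig):
    """Three-stage dual-endpoint design parameters."""

    max_cycle: int = 6
    c1: float = 0.28
    c2: float = 0.28
    p1: float = 0.2
    p2: float = 0.2
    ps1: float = 0.2
    delta: float = 0.1
    stage1_fraction: float = 0.5

    def __post_init__(self) -> None:
        super().__post_init__()
        for name in ("c1", "c2"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValidationError(f"{name} must be in (0,1)")
        for name in ("p1", "p2", "ps1"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValidationError(f"{name} must be in [0,1)")
        if self.delta < 0:
            raise ValidationError("delta must be >= 0")
        if not 0.0 < self.stage1_fraction < 1.0:
            raise ValidationError("stage1_fraction must be in (0,1)")


@dataclass(frozen=True)
class RecommendationResult:
    next_dose: int | None  # None = terminate / no safe dose
    stage: str  # startup, model_tox, stage1, stage2, stage3
    n_enrolled: int = 0
    allowable: tuple[int, ...] | None = None
    efficacious: tuple[int, ...] | None = None
    risks: dict[int, float] | None = None
    predicted_eff: dict[int, float] | None = None
    surface: PosteriorToxSurface | None = None

    @property
    def terminated(self) -> bool:
        return self.next_dose is None


def bayes_risk(
    post: ToxPosterior,
    dose: float,
    target: float,
    method: RiskMethod = "expected_loss",
) -> float:
    """Posterior risk of a dose against the cycle-1 nTTP target.

    ``expected_loss`` is the posterior mean of |cycle-1 mean nTTP - target|
    (the Bayesian risk of the absolute-loss function); ``posterior_mean``
    is the narrative reading |posterior mean - target|, kept as a
    cross-check toggle.  Both rank identically on unimodal posteriors.
    """
    draws = post.mean_nttp_draws(dose, cycle=1)
    if method == "expected_loss":
        return float(np.mean(np.abs(draws - target)))
    if method == "posterior_mean":
        return float(abs(np.mean(draws) - target))
    raise ValidationError(f"unknown risk method {method!r}")


def _tried_doses(data: pd.DataFrame) -> list[int]:
    if len(data) == 0:
        return []
    return sorted(int(d) for d in set(data["dose"]))


def _n_patients(data: pd.DataFrame) -> int:
    if len(data) == 0:
        return 0
    idcol = "uniqueID" if "uniqueID" in data.columns else "subID"
    return data[idcol].nunique()


def startup_rule(data: pd.DataFrame, cfg: DesignConfig) -> int | None:
    """Conventional 3+3 escalation on cycle-1 DLTs at the current (highest tried) dose.

    Returns the next dose level, or None to terminate (>= 2 DLTs at the
    lowest dose).  Only used while fewer than two dose levels have data.
    """
    tried = _tried_doses(data)
    if not tried:
        return cfg.start_dose
    current = max(tried)
    cyc1 = data[(data["dose"] == current) & (data["cycle"] == 1)]
    n = len(cyc1)
    n_dlt = int(cyc1["DLT"].sum())
    pos = cfg.doses.index(current)

    def escalate() -> int:
        return cfg.doses[min(pos + 1, len(cfg.doses) - 1)]

    def deescalate() -> int | None:
        return cfg.doses[pos - 1] if pos > 0 else None

    if n_dlt >= 2:
        return deescalate()
    if n <= 3:
        if n_dlt == 0 and n >= 3:
            return escalate()
        return current  # expand (or cohort still small)
    # n in 4..6+ with at most one DLT
    if n >= 6:
        return escalate() if n_dlt <= 1 else deescalate()
    return current


def recommend_dose_tox(
    data: pd.DataFrame,
    cfg: DesignConfig,
    priors: PriorSpec = PriorSpec(),
    mcmc: McmcOptions = McmcOptions(),
    risk_method: RiskMethod = "expected_loss",
    final: bool = False,
) -> RecommendationResult:
    """Next-dose recommendation for the toxicity-only design.

    With data on fewer than two dose levels the 3+3 run-in rule applies;
    otherwise the mixed model is fitted and the Bayesian-risk minimizer
    returned, capped at one level above the highest tried dose (at the
    highest tried dose when ``final`` is set, for the end-of-trial MTD).
    """
    tried = _tried_doses(data)
    n_enrolled = _n_patients(data)
    if len(tried) < 2:
        if final:
            return RecommendationResult(
                next_dose=tried[-1] if tried else None, stage="startup", n_enrolled=n_enrolled
            )
        return RecommendationResult(
            next_dose=startup_rule(data, cfg), stage="startup", n_enrolled=n_enrolled
        )
    post = fit_tox_lmm(data, priors, mcmc, cycle_coding="linear")
    cap = max(tried) if final else min(max(tried) + 1, cfg.doses[-1])
    candidates = [d for d in cfg.doses if d <= cap]
    risks = {d: bayes_risk(post, d, cfg.tox_target, risk_method) for d in cfg.doses}
    best = min(candidates, key=lambda d: (risks[d], d))
    surface = posterior_tox_surface(post, cfg.doses, cycles=tuple(range(1, cfg.max_cycle + 1)))
    return RecommendationResult(
        next_dose=best,
        stage="model_tox",
        n_enrolled=n_enrolled,
        risks=risks,
        surface=surface,
    )


def stage1_allowable(
    post: ToxPosterior, cfg: DualDesignConfig, doses: Sequence[int]
) -> tuple[int, ...]:
    """Doses passing the cycle-1 safety condition P(mean < c1 | data) > ps1."""
    out = []
    for d in doses:
        frac = float(np.mean(post.mean_nttp_draws(d, cycle=1) < cfg.c1))
        if frac > cfg.ps1:
            out.append(d)
    return tuple(out)


def allowable_doses(
    post: ToxPosterior, cfg: DualDesignConfig, doses: Sequence[int]
) -> tuple[int, ...]:
    """Doses passing both safety conditions (cycle-1 and late-cycle mean nTTP)."""
    out = []
    for d in doses:
        f1 = float(np.mean(post.mean_nttp_draws(d, cycle=1) < cfg.c1))
        f2 = float(np.mean(post.mean_nttp_draws(d, cycle=2) < cfg.c2))
        if f1 > cfg.p1 and f2 > cfg.p2:
            out.append(d)
    return tuple(out)


def softmax_probs(pred_eff: Mapping[int, float]) -> dict[int, float]:
    """Adaptive-randomization probabilities proportional to exp(predicted efficacy)."""
    if not pred_eff:
        raise ValidationError("empty allowable set")
    doses = sorted(pred_eff)
    vals = np.array([pred_eff[d] for d in doses], dtype=float)
    vals -= vals.max()  # translation invariance, numerical safety
    w = np.exp(vals)
    w /= w.sum()
    return {d: float(p) for d, p in zip(doses, w)}


def randomize_stage2(pred_eff: Mapping[int, float], rng: np.random.Generator) -> int:
    """Sample the next cohort's dose with softmax weights on predicted efficacy."""
    probs = softmax_probs(pred_eff)
    doses = sorted(probs)
    return int(rng.choice(doses, p=[probs[d] for d in doses]))


def select_from_predictions(
    pred_eff: Mapping[int, float], delta: float
) -> tuple[tuple[int, ...], int]:
    """Near-optimal set H and the final recommendation (lowest dose in H)."""
    if not pred_eff:
        raise ValidationError("empty allowable set")
    best = max(pred_eff.values())
    H = tuple(sorted(d for d, v in pred_eff.items() if abs(v - best) <= delta))
    return H, H[0]


def final_selection(
    post: JointPosterior, allowable: Sequence[int], delta: float
) -> tuple[tuple[int, ...], int]:
    """Stage-3 selection: H within delta of the best predicted efficacy; pick min(H)."""
    if not allowable:
        raise ValidationError("empty allowable set")
    pred = {int(d): predicted_efficacy(post, d) for d in allowable}
    return select_from_predictions(pred, delta)


def run_trial_dual(
    tox: pd.DataFrame,
    eff: pd.DataFrame,
    cfg: DualDesignConfig,
    priors: PriorSpec = PriorSpec(),
    mcmc: McmcOptions = McmcOptions(),
    rng: np.random.Generator | None = None,
) -> RecommendationResult:
    """One dose decision for the three-stage dual-endpoint design.

    The stage is set by the number of patients enrolled so far: below
    N * stage1_fraction the decision is stage-1 toxicity-driven escalation,
    below N it is stage-2 adaptive randomization, and at N or beyond it is
    the stage-3 final selection.  ``rng`` drives the stage-2 randomization
    (derived from the MCMC seed when omitted).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence((mcmc.seed, 0x52D)))
    n = _n_patients(tox)
    tried = _tried_doses(tox)
    stage1_cut = cfg.trial_size * cfg.stage1_fraction

    if n == 0:
        return RecommendationResult(next_dose=cfg.start_dose, stage="stage1", n_enrolled=0)

    if n < stage1_cut:
        # Toxicity-driven escalation on the safety-restricted candidate set.
        # Early termination is governed by the posterior safety condition
        # (empty allowable set), not by the 3+3 run-in: while only one dose
        # level has data the run-in rule picks the dose but a de-escalation
        # below the lowest dose holds at the lowest dose instead of stopping.
        post = fit_tox_lmm(tox, priors, mcmc, cycle_coding="indicator")
        A1 = stage1_allowable(post, cfg, cfg.doses)
        if not A1:
            return RecommendationResult(next_dose=None, stage="stage1", n_enrolled=n,
                                         allowable=())
        if len(tried) < 2:
            next_dose = startup_rule(tox, cfg)
            if next_dose is None:
                next_dose = cfg.doses[0]
            return RecommendationResult(
                next_dose=next_dose, stage="stage1", n_enrolled=n, allowable=A1
            )
        cap = min(max(tried) + 1, cfg.doses[-1])
        candidates = [d for d in A1 if d <= cap]
        risks = {d: bayes_risk(post, d, cfg.tox_target) for d in cfg.doses}
        next_dose = (
            min(candidates, key=lambda d: (risks[d], d)) if candidates else min(cap, min(A1))
        )
        return RecommendationResult(
            next_dose=next_dose, stage="stage1", n_enrolled=n, allowable=A1, risks=risks
        )

    post = fit_joint_model(tox, eff, priors, mcmc, cycle_coding="indicator")
    A = allowable_doses(post, cfg, cfg.doses)
    surface = posterior_tox_surface(post, cfg.doses, cycles=(1, 2))
    if not A:
        stage = "stage2" if n < cfg.trial_size else "stage3"
        return RecommendationResult(next_dose=None, stage=stage, n_enrolled=n, allowable=(),
                                     surface=surface)

    if n < cfg.trial_size:
        cap = min(max(tried) + 1, cfg.doses[-1])
        candidates = [d for d in A if d <= cap]
        pred = {d: predicted_efficacy(post, d) for d in cfg.doses}
        if candidates:
            next_dose = randomize_stage2({d: pred[d] for d in candidates}, rng)
        else:
            next_dose = min(cap, min(A))
        return RecommendationResult(
            next_dose=next_dose,
            stage="stage2",
            n_enrolled=n,
            allowable=A,
            predicted_eff=pred,
            surface=surface,
        )

    # stage 3: final selection among the allowable doses
    H, rec = final_selection(post, A, cfg.delta)
    pred = {d: predicted_efficacy(post, d) for d in A}
    return RecommendationResult(
        next_dose=rec,
        stage="stage3",
        n_enrolled=n,
        allowable=A,
        efficacious=H,
        predicted_eff=pred,
        surface=surface,
    )
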