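"""Toxicity and efficacy scenario generation for trial simulation.

A simulation scenario is a 4-D probability array (dose x cycle x toxicity
type x grade) giving, for every dose level and treatment cycle, the
distribution of the maximum observed grade of each monitored toxicity type.
The array can be supplied directly (non-parametric path, e.g. built from
historical data) or generated from a proportional-odds cumulative-logit
model in dose and cycle:

    logit P(G <= j) = lambda_j + zeta_l * dose + psi * cycle,   j = 0..3

with increasing intercepts ``lambda_j``, a per-type dose coefficient
``zeta_l`` (negative values shift mass to higher grades as dose rises) and
a common cycle coefficient ``psi``.  Grade probabilities come from
differencing the cumulative probabilities; grade 4 takes the complement.

Scenario "truth" summaries — the mean nTTP at a dose and cycle (by
exhaustive enumeration over all grade combinations, assuming independent
types) and the probability of a cycle-1 DLT — are what simulated operating
characteristics are judged against.  Efficacy outcomes are drawn from beta
distributions matched by moments to a per-dose mean and a common SD.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ValidationError
from .toxicity import N_GRADES, WeightMatrix, compute_nttp, is_dlt


@dataclass(frozen=True)
class POModelSpec:
    """Proportional-odds generator parameters (one spec covers all types)."""

    intercepts: tuple[float, float, float, float]
    dose_coefs: tuple[float, ...]
    cycle_coef: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "intercepts", tuple(float(v) for v in self.intercepts))
        object.__setattr__(self, "dose_coefs", tuple(float(v) for v in self.dose_coefs))
        if len(self.intercepts) != 4:
            raise ValidationError("need exactly 4 cumulative-logit intercepts")
        if any(b <= a for a, b in zip(self.intercepts, self.intercepts[1:])):
            raise ValidationError("intercepts must be strictly increasing")
        if len(self.dose_coefs) < 1:
            raise ValidationError("need at least one per-type dose coefficient")

    @property
    def n_types(self) -> int:
        return len(self.dose_coefs)


@dataclass(frozen=True)
class ToxProbArray:
    """Grade probabilities indexed (dose 1..K, cycle 1..J, type, grade 0..4)."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.ndim != 4 or p.shape[3] != N_GRADES:
            raise ValidationError(f"probs must be K x J x L x {N_GRADES}, got {p.shape}")
        if np.any(p < -1e-12):
            raise ValidationError("probabilities must be non-negative")
        sums = p.sum(axis=3)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValidationError("each (dose, cycle, type) grade slice must sum to 1")

    @property
    def n_doses(self) -> int:
        return self.probs.shape[0]

    @property
    def n_cycles(self) -> int:
        return self.probs.shape[1]

    @property
    def n_types(self) -> int:
        return self.probs.shape[2]

    def grade_probs(self, dose: int, cycle: int) -> np.ndarray:
        """L x 5 slice for a 1-based dose level and cycle."""
        if not (1 <= dose <= self.n_doses and 1 <= cycle <= self.n_cycles):
            raise ValidationError(f"dose {dose} / cycle {cycle} outside the scenario array")
        return self.probs[dose - 1, cycle - 1]


def gen_tox_prob(spec: POModelSpec, n_doses: int, n_cycles: int) -> ToxProbArray:
    """Build the 4-D grade-probability array from a proportional-odds spec.

    Dose enters as the integer level 1..K and cycle as 1..J (no rescaling).
    """
    if n_doses < 1 or n_cycles < 1:
        raise ValidationError("need at least one dose and one cycle")
    doses = np.arange(1, n_doses + 1, dtype=float)
    cycles = np.arange(1, n_cycles + 1, dtype=float)
    lam = np.asarray(spec.intercepts)
    zeta = np.asarray(spec.dose_coefs)
    # cumulative probabilities c_j, shape (K, J, L, 4)
    eta = (
        lam[None, None, None, :]
        + zeta[None, None, :, None] * doses[:, None, None, None]
        + spec.cycle_coef * cycles[None, :, None, None]
    )
    c = expit(eta)
    probs = np.empty((n_doses, n_cycles, len(zeta), N_GRADES))
    probs[..., 0] = c[..., 0]
    probs[..., 1:4] = np.diff(c, axis=-1)
    probs[..., 4] = 1.0 - c[..., 3]
    return ToxProbArray(probs)


def _check_types(probs: ToxProbArray, wm: WeightMatrix) -> None:
    if probs.n_types != wm.n_types:
        raise ValidationError(
            f"scenario has {probs.n_types} toxicity types but weight matrix has {wm.n_types}"
        )


def scenario_pdlt(probs: ToxProbArray, wm: WeightMatrix, dose: int) -> float:
    """True probability of a cycle-1 DLT at a dose, assuming independent types."""
    _check_types(probs, wm)
    slice_ = probs.grade_probs(dose, 1)
    p_no_dlt = 1.0
    for row, min_grade in zip(slice_, wm.dlt_min_grade):
        if min_grade is not None:
            p_no_dlt *= float(row[:min_grade].sum())
    return 1.0 - p_no_dlt


def scenario_mnttp(probs: ToxProbArray, wm: WeightMatrix, dose: int, cycle: int) -> float:
    """True mean nTTP at (dose, cycle) by exhaustive enumeration over 5^L profiles."""
    _check_types(probs, wm)
    slice_ = probs.grade_probs(dose, cycle)
    total = 0.0
    for combo in itertools.product(range(N_GRADES), repeat=wm.n_types):
        p = 1.0
        for l, g in enumerate(combo):
            p *= slice_[l, g]
        if p > 0.0:
            total += p * compute_nttp(combo, wm)
    return total


def scenario_truth(
    probs: ToxProbArray, wm: WeightMatrix, eff_means: Sequence[float] | None = None
) -> pd.DataFrame:
    """Scenario-truth table: mnTTP per cycle, optional mean efficacy, and cycle-1 pDLT.

    Mirrors the layout of the simulator's printed ``$sc`` block: one column
    per dose, rows ``mnTTP.<cycle>`` (plus ``mEFF`` for dual-endpoint
    scenarios) and ``pDLT``.
    """
    doses = range(1, probs.n_doses + 1)
    rows = {
        f"mnTTP.{j}": [scenario_mnttp(probs, wm, d, j) for d in doses]
        for j in range(1, probs.n_cycles + 1)
    }
    if eff_means is not None:
        if len(eff_means) != probs.n_doses:
            raise ValidationError("eff_means length must match the number of doses")
        rows["mEFF"] = [float(v) for v in eff_means]
    rows["pDLT"] = [scenario_pdlt(probs, wm, d) for d in doses]
    return pd.DataFrame(rows, index=[f"Dose {d}" for d in doses]).T


def sample_patient_cycle(
    probs: ToxProbArray,
    dose: int,
    cycle: int,
    wm: WeightMatrix,
    rng: np.random.Generator,
) -> tuple[tuple[int, ...], float, bool]:
    """Draw one patient-cycle toxicity profile; returns (grades, nTTP, DLT)."""
    _check_types(probs, wm)
    slice_ = probs.grade_probs(dose, cycle)
    grades = tuple(int(rng.choice(N_GRADES, p=row)) for row in slice_)
    return grades, compute_nttp(grades, wm), is_dlt(grades, wm)


@dataclass(frozen=True)
class EffScenario:
    """Per-dose mean efficacy in (0,1) plus a common SD, realized as beta draws."""

    mean_eff: tuple[float, ...]
    sd_eff: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean_eff", tuple(float(v) for v in self.mean_eff))
        if self.sd_eff <= 0:
            raise ValidationError("sd_eff must be positive")
        for mu in self.mean_eff:
            beta_moments(mu, self.sd_eff)  # validates each pair

    @property
    def n_doses(self) -> int:
        return len(self.mean_eff)


def beta_moments(mu: float, sd: float) -> tuple[float, float]:
    """Method-of-moments beta shape parameters for mean ``mu`` and SD ``sd``."""
    if not 0.0 < mu < 1.0:
        raise ValidationError(f"mean efficacy must be in (0,1), got {mu}")
    var = sd * sd
    if var >= mu * (1.0 - mu):
        raise ValidationError(
            f"sd={sd} too large for mean {mu}: need sd^2 < mu*(1-mu) for a valid beta"
        )
    common = mu * (1.0 - mu) / var - 1.0
    return mu * common, (1.0 - mu) * common


def sample_efficacy(scen: EffScenario, dose: int, rng: np.random.Generator) -> float:
    """One beta-distributed efficacy outcome for a patient at a 1-based dose level."""
    if not 1 <= dose <= scen.n_doses:
        raise ValidationError(f"dose {dose} outside the efficacy scenario")
    a, b = beta_moments(scen.mean_eff[dose - 1], scen.sd_eff)
    return float(rng.beta(a, b))
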