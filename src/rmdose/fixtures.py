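"""Built-in datasets and synthetic-data generators.

``patdata`` and the head of the efficacy illustration reconstruct the small
example tables verbatim; the remaining fixtures are the parameter sets of
the two worked simulation scenarios and seeded synthetic datasets drawn
from the models themselves (useful for parameter-recovery checks).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .scenarios import EffScenario, POModelSpec
from .toxicity import WeightMatrix

_PATDATA_ROWS = [
    ("cohort1subj1", 1, 1, 1, 1, 0.2, 0),
    ("cohort1subj2", 1, 2, 1, 1, 0.0, 0),
    ("cohort1subj3", 1, 3, 1, 1, 0.0, 0),
    ("cohort1subj1", 1, 1, 1, 2, 0.2, 0),
    ("cohort1subj2", 1, 2, 1, 2, 0.0, 0),
    ("cohort1subj3", 1, 3, 1, 2, 0.2, 1),
    ("cohort2subj1", 2, 1, 2, 1, 0.3, 1),
    ("cohort2subj2", 2, 2, 2, 1, 0.2, 0),
    ("cohort2subj3", 2, 3, 2, 1, 0.2, 0),
]

_EFF_HEAD_ROWS = [
    ("cohort1subject1", 1, 0.014692986),
    ("cohort1subject2", 1, 0.005370450),
    ("cohort1subject3", 1, 0.004324666),
    ("cohort2subject1", 2, 0.005531986),
    ("cohort2subject2", 2, 0.300249297),
    ("cohort2subject3", 2, 0.002631852),
]


def patdata() -> pd.DataFrame:
    """The 9-row two-cohort example trial dataset (doses 1-2, cycles 1-2)."""
    return pd.DataFrame(
        _PATDATA_ROWS,
        columns=["uniqueID", "cohort", "subj", "dose", "cycle", "nTTP", "DLT"],
    )


def eff_dat_head() -> pd.DataFrame:
    """First six rows of the dual-endpoint efficacy illustration."""
    return pd.DataFrame(_EFF_HEAD_ROWS, columns=["subID", "dose", "Efficacy"])


def po_spec_tox() -> POModelSpec:
    """Proportional-odds scenario of the toxicity-only simulation example."""
    return POModelSpec(intercepts=(2.0, 3.0, 4.2, 5.7), dose_coefs=(-0.2, -0.4, -0.7))


def po_spec_dual() -> POModelSpec:
    """Proportional-odds scenario of the dual-endpoint simulation example."""
    return POModelSpec(intercepts=(1.9, 2.3, 2.6, 3.1), dose_coefs=(-0.3, -0.2, -0.25))


def flat_efficacy(n_doses: int = 6, sd: float = 0.2) -> EffScenario:
    """Flat dose-efficacy pattern: mean 0.5 at every dose."""
    return EffScenario(mean_eff=(0.5,) * n_doses, sd_eff=sd)


def synthetic_lmm_data(
    n_patients: int = 200,
    n_cycles: int = 3,
    beta: tuple[float, float, float] = (0.05, 0.05, 0.01),
    sigma_eps: float = 0.1,
    sigma_gamma: float = 0.05,
    doses: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
    seed: int = 0,
) -> pd.DataFrame:
    """Longitudinal nTTP data drawn from the random-intercept toxicity model.

    Doses are assigned round-robin; the cycle covariate is coded t = cycle.
    Response values are not clipped to [0, 1] — recovery checks need the
    exact generative model.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_patients):
        dose = doses[i % len(doses)]
        gamma_i = rng.normal(0.0, sigma_gamma)
        for cycle in range(1, n_cycles + 1):
            y = beta[0] + beta[1] * dose + beta[2] * cycle + gamma_i + rng.normal(0, sigma_eps)
            rows.append((f"pt{i + 1}", 1 + i // 3, i % 3 + 1, dose, cycle, y, 0))
    return pd.DataFrame(
        rows, columns=["uniqueID", "cohort", "subj", "dose", "cycle", "nTTP", "DLT"]
    )


def synthetic_joint_data(
    n_patients: int = 120,
    n_cycles: int = 3,
    beta: tuple[float, float, float] = (0.05, 0.05, 0.01),
    alpha: tuple[float, float, float] = (0.1, 0.15, -0.015),
    nu: float = 0.5,
    sigma_eps: float = 0.1,
    sigma_gamma: float = 0.05,
    sigma_e: float = 0.1,
    doses: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(toxicity, efficacy) tables drawn from the shared-intercept joint model.

    The toxicity cycle covariate is coded 0 for cycle 1 and 1 afterwards,
    matching the dual-endpoint fit.
    """
    rng = np.random.default_rng(seed)
    tox_rows, eff_rows = [], []
    for i in range(n_patients):
        dose = doses[i % len(doses)]
        gamma_i = rng.normal(0.0, sigma_gamma)
        pid = f"pt{i + 1}"
        for cycle in range(1, n_cycles + 1):
            t = 0.0 if cycle == 1 else 1.0
            y = beta[0] + beta[1] * dose + beta[2] * t + gamma_i + rng.normal(0, sigma_eps)
            tox_rows.append((pid, 1 + i // 3, i % 3 + 1, dose, cycle, y, 0))
        e = alpha[0] + alpha[1] * dose + alpha[2] * dose**2 + nu * gamma_i + rng.normal(0, sigma_e)
        eff_rows.append((pid, dose, e))
    tox = pd.DataFrame(
        tox_rows, columns=["uniqueID", "cohort", "subj", "dose", "cycle", "nTTP", "DLT"]
    )
    eff = pd.DataFrame(eff_rows, columns=["subID", "dose", "Efficacy"])
    return tox, eff


FIXTURE_NAMES = (
    "patdata",
    "eff_dat_head",
    "wm_default",
    "po_tox",
    "po_dual",
    "flat_efficacy",
    "synthetic-lmm",
    "synthetic-joint",
)


def make_fixture(name: str, outdir: str | Path, seed: int = 0) -> list[Path]:
    """Write a named fixture to ``outdir``; deterministic given the seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if name == "patdata":
        p = outdir / "patdata.csv"
        patdata().to_csv(p, index=False)
        return [p]
    if name == "eff_dat_head":
        p = outdir / "eff_dat_head.csv"
        eff_dat_head().to_csv(p, index=False)
        return [p]
    if name == "wm_default":
        p = outdir / "weight_matrix.yaml"
        p.write_text(yaml.safe_dump(WeightMatrix.default().to_dict(), sort_keys=False))
        return [p]
    if name in ("po_tox", "po_dual"):
        spec = po_spec_tox() if name == "po_tox" else po_spec_dual()
        p = outdir / f"{name}.yaml"
        p.write_text(
            yaml.safe_dump(
                {
                    "po_model": {
                        "intercepts": list(spec.intercepts),
                        "dose_coefs": list(spec.dose_coefs),
                        "cycle_coef": spec.cycle_coef,
                    }
                },
                sort_keys=False,
            )
        )
        return [p]
    if name == "flat_efficacy":
        scen = flat_efficacy()
        p = outdir / "flat_efficacy.yaml"
        p.write_text(
            yaml.safe_dump(
                {"efficacy": {"mean_eff": list(scen.mean_eff), "sd_eff": scen.sd_eff}},
                sort_keys=False,
            )
        )
        return [p]
    if name == "synthetic-lmm":
        p = outdir / "synthetic_lmm.csv"
        synthetic_lmm_data(seed=seed).to_csv(p, index=False)
        return [p]
    if name == "synthetic-joint":
        tox, eff = synthetic_joint_data(seed=seed)
        p1, p2 = outdir / "synthetic_joint_tox.csv", outdir / "synthetic_joint_eff.csv"
        tox.to_csv(p1, index=False)
        eff.to_csv(p2, index=False)
        return [p1, p2]
    raise ValidationError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
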