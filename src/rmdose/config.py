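"""YAML configuration loading and validation.

A run configuration is a YAML mapping with optional blocks:

.. code-block:: yaml

    weight_matrix:
      toxmax: 2.5
      types:
        - {name: renal, weights: [0, 0.5, 0.75, 1, 1.5], dlt_min_grade: 3}
        - {name: neurological, weights: [0, 0.5, 0.75, 1, 1.5], dlt_min_grade: 3}
        - {name: hematological, weights: [0, 0, 0, 0.5, 1], dlt_min_grade: 4}
    design:
      doses: [1, 2, 3, 4, 5, 6]
      trial_size: 36
      cohort_size: 3
      max_cycle: 5
      start_dose: 1
      tox_target: 0.28
      # dual-endpoint extras: c1, c2, p1, p2, ps1, delta, stage1_fraction
    priors:
      beta_dose: {family: normal, mean: 0, var: 1000}
      s2_epsilon: {family: invgamma, shape: 0.001, scale: 0.001}
    mcmc: {iterations: 2000, burnin: 500, thin: 1, chains: 1, seed: 0}
    po_model:
      intercepts: [2, 3, 4.2, 5.7]
      dose_coefs: [-0.2, -0.4, -0.7]
      cycle_coef: 0
    efficacy: {mean_eff: [0.5, 0.5, 0.5, 0.5, 0.5, 0.5], sd_eff: 0.2}

Every block is optional; omitted blocks fall back to the worked-example
defaults.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .bayes import InvGammaPrior, McmcOptions, NormalPrior, PriorSpec
from .design import DesignConfig, DualDesignConfig
from .errors import ValidationError
from .scenarios import EffScenario, POModelSpec
from .toxicity import WeightMatrix


def load_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"config file not found: {path}")
    try:
        cfg = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ValidationError(f"could not parse YAML config {path}: {exc}") from exc
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValidationError("config root must be a mapping")
    return cfg


def weight_matrix_from_config(cfg: dict) -> WeightMatrix:
    block = cfg.get("weight_matrix")
    return WeightMatrix.default() if block is None else WeightMatrix.from_dict(block)


def _build(cls, block: dict, what: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - fields
    if unknown:
        raise ValidationError(f"unknown {what} keys: {sorted(unknown)}")
    try:
        return cls(**block)
    except TypeError as exc:
        raise ValidationError(f"invalid {what} block: {exc}") from exc


def design_from_config(cfg: dict, dual: bool = False) -> DesignConfig:
    block = dict(cfg.get("design", {}))
    if "doses" in block:
        block["doses"] = tuple(block["doses"])
    cls = DualDesignConfig if dual else DesignConfig
    return _build(cls, block, "design")


def priors_from_config(cfg: dict) -> PriorSpec:
    block = cfg.get("priors", {})
    kwargs = {}
    for name, spec in block.items():
        if not isinstance(spec, dict) or "family" not in spec:
            raise ValidationError(f"prior {name!r} must be a mapping with a 'family' key")
        family = spec["family"]
        if family == "normal":
            kwargs[name] = NormalPrior(float(spec.get("mean", 0.0)), float(spec["var"]))
        elif family == "invgamma":
            kwargs[name] = InvGammaPrior(float(spec["shape"]), float(spec["scale"]))
        else:
            raise ValidationError(f"unknown prior family {family!r} for {name!r}")
    return _build(PriorSpec, kwargs, "priors")


def mcmc_from_config(cfg: dict, seed: int | None = None) -> McmcOptions:
    block = dict(cfg.get("mcmc", {}))
    if seed is not None:
        block["seed"] = seed
    return _build(McmcOptions, block, "mcmc")


def po_spec_from_config(cfg: dict) -> POModelSpec | None:
    block = cfg.get("po_model")
    if block is None:
        return None
    try:
        return POModelSpec(
            intercepts=tuple(block["intercepts"]),
            dose_coefs=tuple(block["dose_coefs"]),
            cycle_coef=float(block.get("cycle_coef", 0.0)),
        )
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"invalid po_model block: {exc}") from exc


def efficacy_from_config(cfg: dict) -> EffScenario | None:
    block = cfg.get("efficacy")
    if block is None:
        return None
    try:
        return EffScenario(mean_eff=tuple(block["mean_eff"]), sd_eff=float(block["sd_eff"]))
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"invalid efficacy block: {exc}") from exc
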