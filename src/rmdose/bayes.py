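"""Bayesian inference for the longitudinal-toxicity and joint toxicity-efficacy models.

Toxicity submodel — a linear mixed model with a patient-level random
intercept for the longitudinal nTTP scores:

    y_ij = beta0 + beta1 * x_i + beta2 * t_j + gamma_i + eps_ij,   beta1 > 0

with eps_ij ~ N(0, s2_eps), gamma_i ~ N(0, s2_gamma).  The dose effect
beta1 is constrained positive (toxicity must not decrease with dose).

Efficacy submodel (dual-endpoint design) — a quadratic dose-response for a
single continuous efficacy outcome per patient, linked to toxicity through
the shared random intercept (compound-symmetry association):

    E_i = alpha0 + alpha1 * x_i + alpha2 * x_i**2 + nu * gamma_i + e_i

with e_i ~ N(0, s2_e).  nu measures the strength of the toxicity-efficacy
association.

All full conditionals are conjugate given gamma, so posterior draws come
from a bespoke Gibbs sampler: (beta0, beta2) as a bivariate Gaussian block,
beta1 from its Gaussian conditional truncated to (0, inf), Gaussian updates
for the gamma_i and the alpha block, and inverse-gamma updates for the
variances.  Priors default to the vague choices of the worked example:
N(0, 1000) on fixed effects and IG(0.001, 0.001) on variances.

Two cycle codings are supported.  The toxicity-only design codes the cycle
covariate as t_j = j (cycle-1 mean evaluated at t = 1).  The dual-endpoint
design codes cycle 1 as t = 0 and all later cycles as t = 1, so that the
safety conditions evaluate the first-cycle mean at t = 0 and a single
aggregate late-cycle mean at t = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .errors import ValidationError

CycleCoding = Literal["linear", "indicator"]


@dataclass(frozen=True)
class NormalPrior:
    mean: float = 0.0
    var: float = 1000.0

    def __post_init__(self) -> None:
        if self.var <= 0:
            raise ValidationError("normal prior variance must be positive")


@dataclass(frozen=True)
class InvGammaPrior:
    shape: float = 0.001
    scale: float = 0.001

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValidationError("inverse-gamma shape and scale must be positive")


@dataclass(frozen=True)
class PriorSpec:
    """Priors for both submodels; defaults mirror the vague worked-example control block."""

    beta0: NormalPrior = NormalPrior(0.0, 1000.0)
    beta_dose: NormalPrior = NormalPrior(0.0, 1000.0)
    beta_cycle: NormalPrior = NormalPrior(0.0, 1000.0)
    s2_gamma: InvGammaPrior = InvGammaPrior(0.001, 0.001)
    s2_epsilon: InvGammaPrior = InvGammaPrior(0.001, 0.001)
    alpha0: NormalPrior = NormalPrior(0.0, 1000.0)
    alpha_dose: NormalPrior = NormalPrior(0.0, 1000.0)
    alpha_dose2: NormalPrior = NormalPrior(0.0, 1000.0)
    nu: NormalPrior = NormalPrior(0.0, 1000.0)
    s2_e: InvGammaPrior = InvGammaPrior(0.001, 0.001)


@dataclass(frozen=True)
class McmcOptions:
    iterations: int = 2000
    burnin: int = 500
    thin: int = 1
    chains: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations <= 0 or self.burnin < 0 or self.thin <= 0 or self.chains <= 0:
            raise ValidationError("MCMC sizes must be positive (burn-in non-negative)")
        if self.burnin >= self.iterations:
            raise ValidationError("burn-in must be smaller than the iteration count")

    @property
    def n_kept(self) -> int:
        return (self.iterations - self.burnin + self.thin - 1) // self.thin


@dataclass(frozen=True)
class ToxPosterior:
    """Retained Gibbs draws for the toxicity mixed model."""

    beta0: np.ndarray
    beta1: np.ndarray
    beta2: np.ndarray
    sigma_eps: np.ndarray
    sigma_gamma: np.ndarray
    gamma: np.ndarray  # (draws, n_patients)
    patient_ids: tuple[str, ...]
    cycle_coding: CycleCoding
    mcmc: McmcOptions

    @property
    def n_draws(self) -> int:
        return self.beta0.shape[0]

    def t_for_cycle(self, cycle: int) -> float:
        if cycle < 1:
            raise ValidationError("cycle must be >= 1")
        if self.cycle_coding == "linear":
            return float(cycle)
        return 0.0 if cycle == 1 else 1.0

    def mean_nttp_draws(self, dose: float, cycle: int = 1) -> np.ndarray:
        """Draw-wise population mean nTTP at a dose and cycle (random intercept excluded)."""
        t = self.t_for_cycle(cycle)
        return self.beta0 + self.beta1 * dose + self.beta2 * t


@dataclass(frozen=True)
class JointPosterior(ToxPosterior):
    alpha0: np.ndarray = field(default_factory=lambda: np.empty(0))
    alpha1: np.ndarray = field(default_factory=lambda: np.empty(0))
    alpha2: np.ndarray = field(default_factory=lambda: np.empty(0))
    nu: np.ndarray = field(default_factory=lambda: np.empty(0))
    sigma_e: np.ndarray = field(default_factory=lambda: np.empty(0))

    def predicted_efficacy_draws(self, dose: float) -> np.ndarray:
        return self.alpha0 + self.alpha1 * dose + self.alpha2 * dose * dose


@dataclass(frozen=True)
class PosteriorToxSurface:
    """Posterior summaries of the population mean nTTP per (cycle, dose)."""

    table: pd.DataFrame  # MultiIndex rows (cycle, statistic), columns "Dose k"

    STATS = ("mean", "sd", "median", "2.5%", "25%", "50%", "75%", "97.5%")

    def mean(self, dose: int, cycle: int) -> float:
        return float(self.table.loc[(cycle, "mean"), f"Dose {dose}"])

    def cycle_block(self, cycle: int) -> pd.DataFrame:
        return self.table.loc[cycle]


def _sample_truncnorm_pos(mu: float, sd: float, rng: np.random.Generator) -> float:
    """One draw from N(mu, sd^2) truncated to (0, inf)."""
    alpha = -mu / sd
    if alpha < 8.0:
        tail = ndtr(-alpha)  # P(Z > alpha)
        v = max(rng.random() * tail, 5e-324)
        return mu + sd * float(-ndtri(v))
    # far tail: exponential rejection (robust when mu << 0)
    lam = 0.5 * (alpha + math.sqrt(alpha * alpha + 4.0))
    while True:
        z = alpha + rng.exponential(1.0 / lam)
        if rng.random() <= math.exp(-0.5 * (z - lam) ** 2):
            return mu + sd * z


def _sample_invgamma(shape: float, scale: float, rng: np.random.Generator) -> float:
    return float(scale / rng.gamma(shape))


def _id_column(df: pd.DataFrame, candidates: tuple[str, ...]) -> str:
    for c in candidates:
        if c in df.columns:
            return c
    raise ValidationError(f"no patient-id column found (expected one of {candidates})")


def _prepare_tox(data: pd.DataFrame, cycle_coding: CycleCoding):
    if len(data) == 0:
        raise ValidationError("toxicity data is empty")
    for col in ("dose", "cycle", "nTTP"):
        if col not in data.columns:
            raise ValidationError(f"toxicity table is missing column {col!r}")
    idcol = _id_column(data, ("uniqueID", "subID", "patient"))
    ids = data[idcol].astype(str).to_numpy()
    patient_ids = tuple(dict.fromkeys(ids))  # stable order of appearance
    index = {pid: k for k, pid in enumerate(patient_ids)}
    pat = np.array([index[i] for i in ids])
    x = data["dose"].to_numpy(dtype=float)
    cyc = data["cycle"].to_numpy(dtype=float)
    if np.any(cyc < 1):
        raise ValidationError("cycles must be >= 1")
    if np.any(x < 1):
        raise ValidationError("dose levels must be >= 1")
    t = cyc if cycle_coding == "linear" else (cyc > 1).astype(float)
    y = data["nTTP"].to_numpy(dtype=float)
    return y, x, t, pat, patient_ids


def _gibbs_chain(
    y: np.ndarray,
    x: np.ndarray,
    t: np.ndarray,
    pat: np.ndarray,
    n_pat: int,
    priors: PriorSpec,
    mcmc: McmcOptions,
    rng: np.random.Generator,
    eff: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> dict[str, np.ndarray]:
    """One Gibbs chain; ``eff`` = (E, x_eff, pat_eff) activates the joint model."""
    n = y.shape[0]
    # precomputed design quantities
    X = np.column_stack([np.ones(n), x, t])  # (beta0, beta1, beta2)
    XtX = X.T @ X
    Sxx = float(x @ x)
    prior_mb = np.array([priors.beta0.mean, priors.beta_dose.mean, priors.beta_cycle.mean])
    prior_vbinv = np.diag(
        [1.0 / priors.beta0.var, 1.0 / priors.beta_dose.var, 1.0 / priors.beta_cycle.var]
    )

    joint = eff is not None
    if joint:
        E, xe, pat_e = eff
        ne = E.shape[0]
        Z = np.column_stack([np.ones(ne), xe, xe * xe])
        ZtZ = Z.T @ Z
        prior_ma = np.array([priors.alpha0.mean, priors.alpha_dose.mean, priors.alpha_dose2.mean])
        prior_vainv = np.diag(
            [1.0 / priors.alpha0.var, 1.0 / priors.alpha_dose.var, 1.0 / priors.alpha_dose2.var]
        )

    # deterministic warm start
    beta0, beta1, beta2 = 0.0, 0.01, 0.0
    s2_eps = s2_gam = 1.0
    gamma = np.zeros(n_pat)
    alpha = np.zeros(3)
    nu = 0.0
    s2_e = 1.0

    counts = np.bincount(pat, minlength=n_pat).astype(float)
    kept = mcmc.n_kept
    out = {k: np.empty(kept) for k in ("beta0", "beta1", "beta2", "sigma_eps", "sigma_gamma")}
    out["gamma"] = np.empty((kept, n_pat))
    if joint:
        out.update({k: np.empty(kept) for k in ("alpha0", "alpha1", "alpha2", "nu", "sigma_e")})

    k = 0
    for it in range(mcmc.iterations):
        yg = y - gamma[pat]
        # (beta0, beta1, beta2) block from its trivariate Gaussian conditional
        # truncated to beta1 > 0: rejection from the untruncated conditional,
        # falling back to a scalar truncated update when acceptance is poor
        prec = XtX / s2_eps + prior_vbinv
        rhs = X.T @ yg / s2_eps + prior_vbinv @ prior_mb
        L = np.linalg.cholesky(prec)
        mean_b = np.linalg.solve(prec, rhs)
        for _ in range(64):
            b = mean_b + np.linalg.solve(L.T, rng.standard_normal(3))
            if b[1] > 0.0:
                beta0, beta1, beta2 = float(b[0]), float(b[1]), float(b[2])
                break
        else:
            beta0, beta2 = float(b[0]), float(b[2])
            r1 = yg - beta0 - beta2 * t
            prec1 = Sxx / s2_eps + 1.0 / priors.beta_dose.var
            mu1 = (
                float(x @ r1) / s2_eps + priors.beta_dose.mean / priors.beta_dose.var
            ) / prec1
            beta1 = _sample_truncnorm_pos(mu1, 1.0 / math.sqrt(prec1), rng)
        # random intercepts
        res = y - beta0 - beta1 * x - beta2 * t
        prec_g = counts / s2_eps + 1.0 / s2_gam
        num_g = np.bincount(pat, weights=res, minlength=n_pat) / s2_eps
        if joint:
            eff_res = E - Z @ alpha
            prec_g = prec_g.copy()
            np.add.at(prec_g, pat_e, nu * nu / s2_e)
            np.add.at(num_g, pat_e, nu * eff_res / s2_e)
        gamma = num_g / prec_g + rng.standard_normal(n_pat) / np.sqrt(prec_g)
        # variances
        s2_gam = _sample_invgamma(
            priors.s2_gamma.shape + 0.5 * n_pat,
            priors.s2_gamma.scale + 0.5 * float(gamma @ gamma),
            rng,
        )
        e_tox = res - gamma[pat]
        s2_eps = _sample_invgamma(
            priors.s2_epsilon.shape + 0.5 * n,
            priors.s2_epsilon.scale + 0.5 * float(e_tox @ e_tox),
            rng,
        )
        if joint:
            # alpha block
            target = E - nu * gamma[pat_e]
            prec_a = ZtZ / s2_e + prior_vainv
            rhs_a = Z.T @ target / s2_e + prior_vainv @ prior_ma
            La = np.linalg.cholesky(prec_a)
            mean_a = np.linalg.solve(prec_a, rhs_a)
            alpha = mean_a + np.linalg.solve(La.T, rng.standard_normal(3))
            # shared-intercept loading nu
            g_e = gamma[pat_e]
            resid_e = E - Z @ alpha
            prec_nu = float(g_e @ g_e) / s2_e + 1.0 / priors.nu.var
            mu_nu = (float(g_e @ resid_e) / s2_e + priors.nu.mean / priors.nu.var) / prec_nu
            nu = float(rng.normal(mu_nu, 1.0 / math.sqrt(prec_nu)))
            e_eff = resid_e - nu * g_e
            s2_e = _sample_invgamma(
                priors.s2_e.shape + 0.5 * ne,
                priors.s2_e.scale + 0.5 * float(e_eff @ e_eff),
                rng,
            )
        if it >= mcmc.burnin and (it - mcmc.burnin) % mcmc.thin == 0:
            out["beta0"][k] = beta0
            out["beta1"][k] = beta1
            out["beta2"][k] = beta2
            out["sigma_eps"][k] = math.sqrt(s2_eps)
            out["sigma_gamma"][k] = math.sqrt(s2_gam)
            out["gamma"][k] = gamma
            if joint:
                out["alpha0"][k] = alpha[0]
                out["alpha1"][k] = alpha[1]
                out["alpha2"][k] = alpha[2]
                out["nu"][k] = nu
                out["sigma_e"][k] = math.sqrt(s2_e)
            k += 1
    return out


def _run_chains(y, x, t, pat, n_pat, priors, mcmc, eff=None) -> dict[str, np.ndarray]:
    streams = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
    chains = [
        _gibbs_chain(y, x, t, pat, n_pat, priors, mcmc, np.random.default_rng(s), eff)
        for s in streams
    ]
    return {k: np.concatenate([c[k] for c in chains], axis=0) for k in chains[0]}


def fit_tox_lmm(
    data: pd.DataFrame,
    priors: PriorSpec = PriorSpec(),
    mcmc: McmcOptions = McmcOptions(),
    cycle_coding: CycleCoding = "linear",
) -> ToxPosterior:
    """Fit the random-intercept toxicity model to a longitudinal nTTP table.

    ``data`` needs columns ``dose``, ``cycle``, ``nTTP`` and a patient id
    (``uniqueID`` or ``subID``).  Returns retained post-burn-in draws.
    """
    y, x, t, pat, ids = _prepare_tox(data, cycle_coding)
    draws = _run_chains(y, x, t, pat, len(ids), priors, mcmc)
    return ToxPosterior(
        beta0=draws["beta0"],
        beta1=draws["beta1"],
        beta2=draws["beta2"],
        sigma_eps=draws["sigma_eps"],
        sigma_gamma=draws["sigma_gamma"],
        gamma=draws["gamma"],
        patient_ids=ids,
        cycle_coding=cycle_coding,
        mcmc=mcmc,
    )


def fit_joint_model(
    tox: pd.DataFrame,
    eff: pd.DataFrame,
    priors: PriorSpec = PriorSpec(),
    mcmc: McmcOptions = McmcOptions(),
    cycle_coding: CycleCoding = "indicator",
) -> JointPosterior:
    """Fit the shared-random-intercept toxicity-efficacy joint model.

    Every efficacy patient must appear in the toxicity table (the random
    intercept is shared).  Efficacy is one record per patient with columns
    ``subID``/``uniqueID``, ``dose``, ``Efficacy``.
    """
    y, x, t, pat, ids = _prepare_tox(tox, cycle_coding)
    for col in ("dose", "Efficacy"):
        if col not in eff.columns:
            raise ValidationError(f"efficacy table is missing column {col!r}")
    idcol = _id_column(eff, ("subID", "uniqueID", "patient"))
    index = {pid: k for k, pid in enumerate(ids)}
    eff_ids = eff[idcol].astype(str).to_numpy()
    orphans = [i for i in eff_ids if i not in index]
    if orphans:
        raise ValidationError(
            f"efficacy patients missing from the toxicity table: {orphans[:5]}"
        )
    if len(set(eff_ids)) != len(eff_ids):
        raise ValidationError("duplicate patient ids in the efficacy table")
    E = eff["Efficacy"].to_numpy(dtype=float)
    xe = eff["dose"].to_numpy(dtype=float)
    pat_e = np.array([index[i] for i in eff_ids])
    draws = _run_chains(y, x, t, pat, len(ids), priors, mcmc, eff=(E, xe, pat_e))
    return JointPosterior(
        beta0=draws["beta0"],
        beta1=draws["beta1"],
        beta2=draws["beta2"],
        sigma_eps=draws["sigma_eps"],
        sigma_gamma=draws["sigma_gamma"],
        gamma=draws["gamma"],
        patient_ids=ids,
        cycle_coding=cycle_coding,
        mcmc=mcmc,
        alpha0=draws["alpha0"],
        alpha1=draws["alpha1"],
        alpha2=draws["alpha2"],
        nu=draws["nu"],
        sigma_e=draws["sigma_e"],
    )


def posterior_tox_surface(
    post: ToxPosterior, doses: tuple[int, ...], cycles: tuple[int, ...] = (1,)
) -> PosteriorToxSurface:
    """Summaries of the population mean nTTP beta0 + beta1*x + beta2*t per (cycle, dose)."""
    if post.n_draws == 0:
        raise ValidationError("posterior has no retained draws")
    qs = (2.5, 25, 50, 75, 97.5)
    rows = {}
    for cyc in cycles:
        for dose in doses:
            d = post.mean_nttp_draws(dose, cyc)
            quants = np.percentile(d, qs)
            rows[(cyc, dose)] = [
                float(np.mean(d)),
                float(np.std(d, ddof=1)) if d.size > 1 else 0.0,
                float(np.median(d)),
                *[float(v) for v in quants],
            ]
    table = pd.DataFrame(
        {
            (cyc, stat): [rows[(cyc, dose)][i] for dose in doses]
            for cyc in cycles
            for i, stat in enumerate(PosteriorToxSurface.STATS)
        },
        index=[f"Dose {d}" for d in doses],
    ).T
    table.index = pd.MultiIndex.from_tuples(table.index, names=["cycle", "statistic"])
    return PosteriorToxSurface(table=table)


def predicted_efficacy(post: JointPosterior, dose: float) -> float:
    """Posterior mean efficacy alpha0 + alpha1*x + alpha2*x^2 (random effect excluded)."""
    if post.n_draws == 0:
        raise ValidationError("posterior has no retained draws")
    return float(np.mean(post.predicted_efficacy_draws(dose)))
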