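"""Dose-decision engine: Bayesian risk, 3+3 run-in, allowability, randomization, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rmdose import (
    DesignConfig,
    DualDesignConfig,
    McmcOptions,
    ToxPosterior,
    ValidationError,
    allowable_doses,
    bayes_risk,
    recommend_dose_tox,
    run_trial_dual,
    softmax_probs,
    startup_rule,
)
from rmdose.design import randomize_stage2, select_from_predictions, stage1_allowable

MCMC = McmcOptions(iterations=1500, burnin=400, seed=3)
COLS = ["uniqueID", "cohort", "subj", "dose", "cycle", "nTTP", "DLT"]


def _posterior(beta0, beta1, beta2, coding="linear"):
    b0, b1, b2 = (np.asarray(v, dtype=float) for v in (beta0, beta1, beta2))
    n = b0.size
    return ToxPosterior(
        beta0=b0, beta1=b1, beta2=b2,
        sigma_eps=np.full(n, 0.1), sigma_gamma=np.full(n, 0.1), gamma=np.zeros((n, 1)),
        patient_ids=("p1",), cycle_coding=coding, mcmc=McmcOptions(seed=0),
    )


def _tox_df(rows):
    return pd.DataFrame(rows, columns=COLS)


def _cohort(cohort, dose, dlts, nttps=None, cycle=1):
    nttps = nttps if nttps is not None else [0.4 if d else 0.0 for d in dlts]
    return [
        (f"c{cohort}s{i + 1}", cohort, i + 1, dose, cycle, y, d)
        for i, (y, d) in enumerate(zip(nttps, dlts))
    ]


class TestBayesRisk:
    def test_zero_loss_at_target(self):
        post = _posterior([0.08] * 3, [0.05] * 3, [0.10] * 3)  # cycle-1 mean 0.28 at dose 2
        assert bayes_risk(post, 2, 0.28) == pytest.approx(0.0)

    def test_two_draw_expected_absolute_loss(self):
        # cycle-1 means at dose 1: 0.2 and 0.4 -> (0.08 + 0.12) / 2
        post = _posterior([0.1, 0.3], [0.05, 0.05], [0.05, 0.05])
        assert bayes_risk(post, 1, 0.28) == pytest.approx(0.10)

    def test_posterior_mean_variant(self):
        post = _posterior([0.1, 0.3], [0.05, 0.05], [0.05, 0.05])
        assert bayes_risk(post, 1, 0.28, method="posterior_mean") == pytest.approx(0.02)


class TestStartupRule:
    cfg = DesignConfig()

    def test_empty_data_starts_at_start_dose(self):
        assert startup_rule(_tox_df([]), self.cfg) == 1
        rec = recommend_dose_tox(_tox_df([]), self.cfg)
        assert rec.next_dose == 1 and rec.stage == "startup"

    @pytest.mark.parametrize(
        "dlts6, expected",
        [
            ((0, 0, 0), 2),          # 0/3 -> escalate
            ((1, 0, 0), 1),          # 1/3 -> expand the same dose
            ((1, 1, 0), None),       # 2/3 at the lowest dose -> terminate
            ((0, 0, 0, 1, 0, 0), 2), # 1/6 -> escalate
            ((1, 0, 0, 1, 0, 0), None),  # 2/6 at the lowest dose -> terminate
        ],
    )
    def test_rule_table_at_lowest_dose(self, dlts6, expected):
        data = _tox_df(_cohort(1, 1, dlts6))
        assert startup_rule(data, self.cfg) == expected

    def test_deescalation_above_lowest_dose(self):
        rows = _cohort(1, 2, (1, 1, 0))
        assert startup_rule(_tox_df(rows), self.cfg) == 1


class TestModelRecommendation:
    def test_patdata_recommends_dose_two(self, patdata_df):
        rec = recommend_dose_tox(patdata_df, DesignConfig(), mcmc=MCMC)
        assert rec.stage == "model_tox"
        assert rec.next_dose == 2
        assert rec.risks[2] == min(rec.risks[d] for d in range(1, 7))

    def test_no_skipping_caps_at_highest_tried_plus_one(self):
        # sub-target toxicity everywhere: unconstrained argmin is dose 6
        rows = _cohort(1, 1, (0, 0, 0), nttps=(0.0, 0.01, 0.0)) + _cohort(
            2, 2, (0, 0, 0), nttps=(0.01, 0.02, 0.0)
        )
        rec = recommend_dose_tox(_tox_df(rows), DesignConfig(), mcmc=MCMC)
        assert rec.next_dose == 3
        assert min(rec.risks, key=rec.risks.get) >= 5


class TestAllowability:
    def test_point_mass_conditions(self):
        # cycle-1 means 0.1d under indicator coding; beta2 = 0 so late means match
        post = _posterior([0.0] * 4, [0.1] * 4, [0.0] * 4, coding="indicator")
        cfg = DualDesignConfig(c1=0.28, c2=0.28, p1=0.2, p2=0.2, tox_target=0.28)
        assert allowable_doses(post, cfg, (1, 2, 3, 4)) == (1, 2)

    def test_diffuse_posterior_with_zero_cutoffs_allows_everything(self):
        rng = np.random.default_rng(0)
        post = _posterior(rng.normal(0.1, 0.2, 200), rng.uniform(0.01, 0.1, 200),
                          rng.normal(0, 0.05, 200), coding="indicator")
        cfg = DualDesignConfig(p1=0.0, p2=0.0, tox_target=0.28)
        assert allowable_doses(post, cfg, (1, 2, 3, 4, 5, 6)) == (1, 2, 3, 4, 5, 6)

    def test_unattainable_bound_empties_the_set(self):
        post = _posterior([0.2] * 4, [0.1] * 4, [0.0] * 4, coding="indicator")
        cfg = DualDesignConfig(c1=0.001, c2=0.001, tox_target=0.28)
        assert allowable_doses(post, cfg, (1, 2, 3)) == ()
        assert stage1_allowable(post, cfg, (1, 2, 3)) == ()


class TestRandomization:
    def test_symmetric_and_shifted_probabilities(self):
        assert softmax_probs({1: 0.4, 2: 0.4, 3: 0.4}) == {
            1: pytest.approx(1 / 3), 2: pytest.approx(1 / 3), 3: pytest.approx(1 / 3)
        }
        probs = softmax_probs({1: 0.0, 2: 1.0})
        assert probs[1] == pytest.approx(1 / (1 + np.e))
        assert probs[2] == pytest.approx(np.e / (1 + np.e))

    @given(
        vals=st.lists(st.floats(-5, 5), min_size=2, max_size=6),
        shift=st.floats(-100, 100),
    )
    def test_translation_invariance_and_conservation(self, vals, shift):
        base = {i + 1: v for i, v in enumerate(vals)}
        shifted = {d: v + shift for d, v in base.items()}
        p1, p2 = softmax_probs(base), softmax_probs(shifted)
        assert sum(p1.values()) == pytest.approx(1.0)
        for d in base:
            assert p1[d] == pytest.approx(p2[d], abs=1e-9)

    def test_empirical_allocation_matches_probabilities(self):
        pred = {1: 0.2, 2: 0.5, 3: 0.4}
        probs = softmax_probs(pred)
        rng = np.random.default_rng(8)
        n = 20_000
        draws = np.array([randomize_stage2(pred, rng) for _ in range(n)])
        for d, p in probs.items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(np.mean(draws == d) - p) < 3 * se

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            softmax_probs({})


class TestFinalSelection:
    def test_near_optimal_set(self):
        H, rec = select_from_predictions({1: 0.2, 2: 0.5, 3: 0.51}, delta=0.02)
        assert H == (2, 3) and rec == 2

    def test_zero_delta_unique_maximizer(self):
        H, rec = select_from_predictions({1: 0.2, 2: 0.5, 3: 0.4}, delta=0.0)
        assert H == (2,) and rec == 2

    def test_flat_efficacy_returns_lowest_allowable(self):
        H, rec = select_from_predictions({2: 0.5, 4: 0.5, 5: 0.5}, delta=0.0)
        assert H == (2, 4, 5) and rec == 2


class TestDualDecision:
    def test_no_data_starts_trial(self, dual_cfg):
        empty = _tox_df([])
        eff = pd.DataFrame(columns=["subID", "dose", "Efficacy"])
        rec = run_trial_dual(empty, eff, dual_cfg, mcmc=MCMC)
        assert rec.next_dose == 1 and rec.stage == "stage1"

    def test_overtoxic_data_terminates(self, dual_cfg):
        rows = _cohort(1, 1, (1, 1, 1), nttps=(0.6, 0.55, 0.65)) + _cohort(
            2, 1, (1, 1, 0), nttps=(0.6, 0.62, 0.58)
        )
        eff = pd.DataFrame(columns=["subID", "dose", "Efficacy"])
        rec = run_trial_dual(_tox_df(rows), eff, dual_cfg, mcmc=MCMC)
        assert rec.terminated and rec.allowable == ()
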