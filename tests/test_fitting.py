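"""Likelihoods, ML estimation, fit indices and model comparison."""

import math

import numpy as np
import pytest
from scipy import stats

from selfworth import (
    ChoiceParams,
    ModelSpec,
    SelfWorthParams,
    choice_nll,
    compare_models,
    esv_trajectory,
    fit_choice_model,
    fit_selfworth_model,
    model_free_feedback_effect,
    pseudo_r2,
    selfworth_nll,
    selfworth_series,
)
from selfworth.fitting import bic


class TestChoiceNll:
    def test_beta_zero_is_chance_loglik(self, default_schedule):
        log = default_schedule.copy()
        rng = np.random.default_rng(0)
        log.choice = rng.integers(0, 2, log.n_trials).astype(float)
        params = ChoiceParams(eta=0.1, beta=0.0, v0_hi=0.8, v0_lo=0.2)
        assert choice_nll(params, log) == pytest.approx(log.n_trials * math.log(2))

    def test_near_deterministic_agent_scores_near_zero(self, subject_factory):
        log = subject_factory(eta=0.05, beta=50.0, schedule_seed=1, agent_seed=2)
        params = ChoiceParams(eta=0.05, beta=50.0, v0_hi=0.8, v0_lo=0.2)
        assert choice_nll(params, log) < 0.01 * log.n_trials

    def test_generating_params_dominate_perturbed_on_average(self, subject_factory):
        gen = ChoiceParams(eta=0.1, beta=8.0, v0_hi=0.8, v0_lo=0.2)
        shifted = ChoiceParams(eta=0.4, beta=8.0, v0_hi=0.8, v0_lo=0.2)
        deltas = []
        for i in range(100):
            log = subject_factory(eta=0.1, schedule_seed=300 + i, agent_seed=400 + i)
            deltas.append(choice_nll(shifted, log) - choice_nll(gen, log))
        assert np.mean(deltas) > 0

    def test_missing_choices_rejected(self, default_schedule):
        params = ChoiceParams(eta=0.1, beta=1.0, v0_hi=0.8, v0_lo=0.2)
        with pytest.raises(ValueError, match="choices"):
            choice_nll(params, default_schedule)


class TestFitIndices:
    @pytest.mark.parametrize(
        "nll,n,expected",
        [
            (100 * math.log(2), 100, 0.0),
            (0.0, 50, 1.0),
            (5 * math.log(2), 10, 0.5),
        ],
    )
    def test_pseudo_r2_values(self, nll, n, expected):
        assert pseudo_r2(nll, n) == pytest.approx(expected)

    def test_bic_hand_computation(self):
        assert bic(100.0, 4, 180) == pytest.approx(220.772, abs=5e-4)


class TestSelfworthNll:
    def _fitted_traj(self, log, cp):
        return esv_trajectory(cp, log)

    def test_zero_residuals_unit_sigma(self, subject_factory):
        log = subject_factory(schedule_seed=5, agent_seed=6)
        cp = ChoiceParams(eta=0.05, beta=8.0, v0_hi=0.8, v0_lo=0.2)
        traj = self._fitted_traj(log, cp)
        params = SelfWorthParams(w0=0.7, w1=0.05, gamma=0.5, sigma=1.0)
        traj = selfworth_series(params, traj)
        log.rating[log.probe] = np.clip(traj.predicted_self_worth[log.probe], 0, 1)
        n = log.n_probes
        assert selfworth_nll(params, log, traj) == pytest.approx(n * math.log(math.sqrt(2 * math.pi)))

    def test_matches_gaussian_density_oracle(self, subject_factory):
        log = subject_factory(schedule_seed=7, agent_seed=8)
        cp = ChoiceParams(eta=0.05, beta=8.0, v0_hi=0.8, v0_lo=0.2)
        traj = self._fitted_traj(log, cp)
        params = SelfWorthParams(w0=0.65, w1=0.04, gamma=0.3, sigma=0.09)
        traj2 = selfworth_series(params, traj)
        expected = -stats.norm.logpdf(
            log.rating[log.probe], loc=traj2.predicted_self_worth[log.probe], scale=0.09
        ).sum()
        assert selfworth_nll(params, log, traj) == pytest.approx(expected, abs=1e-10)

    def test_doubling_residuals_increases_nll(self, subject_factory):
        log = subject_factory(schedule_seed=9, agent_seed=10)
        cp = ChoiceParams(eta=0.05, beta=8.0, v0_hi=0.8, v0_lo=0.2)
        traj = self._fitted_traj(log, cp)
        params = SelfWorthParams(w0=0.7, w1=0.05, gamma=0.5, sigma=0.1)
        traj = selfworth_series(params, traj)
        base = selfworth_nll(params, log, traj)
        pred = traj.predicted_self_worth[log.probe]
        log2 = log.copy()
        log2.rating[log2.probe] = np.clip(pred + 2 * (log.rating[log.probe] - pred), 0, 1)
        assert selfworth_nll(params, log2, traj) > base


class TestFitChoiceModel:
    def test_refit_same_seed_is_identical(self, subject_factory):
        log = subject_factory(schedule_seed=20, agent_seed=21)
        a = fit_choice_model(log, n_restarts=5, seed=3)
        b = fit_choice_model(log, n_restarts=5, seed=3)
        assert a.params == b.params
        assert a.nll == b.nll
        assert a.best_restart_seed == b.best_restart_seed

    def test_no_learning_variant_freezes_eta(self, subject_factory):
        log = subject_factory(schedule_seed=22, agent_seed=23)
        fit = fit_choice_model(log, ModelSpec("nl", "no_learning", None), n_restarts=5, seed=0)
        assert fit.params["eta"] == 0.0
        assert fit.k == 3

    def test_nested_model_likelihood_ordering(self, subject_factory):
        # the full model can always mimic the restricted one
        for i in range(3):
            log = subject_factory(eta=0.0, schedule_seed=30 + i, agent_seed=40 + i)
            full = fit_choice_model(log, ModelSpec("full"), n_restarts=10, seed=i)
            nl = fit_choice_model(log, ModelSpec("nl", "no_learning", None), n_restarts=10, seed=i)
            assert full.nll <= nl.nll + 1e-3

    def test_fitted_model_beats_chance_accuracy(self, subject_factory):
        log = subject_factory(schedule_seed=50, agent_seed=51)
        fit = fit_choice_model(log, n_restarts=10, seed=0)
        traj = esv_trajectory(fit.choice_params, log)
        accuracy = ((traj.choice_prob >= 0.5).astype(float) == log.choice).mean()
        assert accuracy >= 0.5


class TestFitSelfworthModel:
    def test_noiseless_recovery(self, default_schedule):
        cp = ChoiceParams(eta=0.05, beta=8.0, v0_hi=0.8, v0_lo=0.2)
        log = default_schedule.copy()
        traj = esv_trajectory(cp, log)
        true = SelfWorthParams(w0=0.6, w1=0.1, gamma=0.5, sigma=0.01)
        traj = selfworth_series(true, traj)
        log.rating = np.where(log.probe, traj.predicted_self_worth, np.nan)
        log.choice = np.zeros(log.n_trials)
        fit = fit_selfworth_model(log, traj)
        assert fit.params["w0"] == pytest.approx(0.6, abs=0.02)
        assert fit.params["w1"] == pytest.approx(0.1, abs=0.02)
        assert fit.params["gamma"] == pytest.approx(0.5, abs=0.02)
        assert fit.r2 > 0.99

    def test_null_w1_estimates_center_on_zero(self, subject_factory):
        w1s = []
        for i in range(100):
            log = subject_factory(w1=0.0, sigma=0.05, schedule_seed=600 + i, agent_seed=700 + i)
            cp = ChoiceParams(eta=0.05, beta=8.0, v0_hi=0.8, v0_lo=0.2)
            traj = esv_trajectory(cp, log)
            w1s.append(fit_selfworth_model(log, traj).params["w1"])
        w1s = np.array(w1s)
        # mean within 2 SE of zero
        assert abs(w1s.mean()) < 2 * w1s.std(ddof=1) / math.sqrt(len(w1s))

    def test_constant_ratings_degenerate_convention(self, default_schedule):
        cp = ChoiceParams(eta=0.05, beta=8.0, v0_hi=0.8, v0_lo=0.2)
        log = default_schedule.copy()
        traj = esv_trajectory(cp, log)
        log.rating = np.where(log.probe, 0.5, np.nan)
        fit = fit_selfworth_model(log, traj)
        assert fit.params["w1"] == 0.0
        assert fit.r2 == 0.0
        assert "constant_ratings" in fit.flags

    def test_too_few_ratings_rejected(self, default_schedule):
        cp = ChoiceParams(eta=0.05, beta=8.0, v0_hi=0.8, v0_lo=0.2)
        log = default_schedule.copy()
        traj = esv_trajectory(cp, log)
        probe_idx = np.flatnonzero(log.probe)
        log.probe[:] = False
        log.probe[probe_idx[:2]] = True
        log.rating = np.where(log.probe, 0.5, np.nan)
        with pytest.raises(ValueError, match="at least 3"):
            fit_selfworth_model(log, traj)


class TestCompareModels:
    def test_single_spec_wins_trivially(self, subject_factory):
        logs = [subject_factory(schedule_seed=70, agent_seed=71)]
        res = compare_models(logs, [ModelSpec("only", "full", None)], n_restarts=3, seed=0)
        assert res["winner"] == "only"

    def test_recovery_sharpens_with_more_data(self):
        # median |eta_hat - eta| at 3x trials <= that at 1x
        from selfworth import TaskDesign, make_schedule
        from selfworth.cohort import simulate_subject

        cp = ChoiceParams(eta=0.1, beta=8.0, v0_hi=0.8, v0_lo=0.2)
        sp = SelfWorthParams(w0=0.7, w1=0.05, gamma=0.5, sigma=0.05)
        designs = {
            1: TaskDesign(),
            3: TaskDesign(trials_per_rater=3, n_probes=225),
        }
        errs = {}
        for mult, design in designs.items():
            vals = []
            for i in range(25):
                log = simulate_subject(cp, sp, make_schedule(design, 800 + i), 900 + i)
                fit = fit_choice_model(log, n_restarts=8, seed=i)
                vals.append(abs(fit.params["eta"] - 0.1))
            errs[mult] = np.median(vals)
        assert errs[3] <= errs[1]


class TestModelFreeFeedbackEffect:
    def test_positive_weight_yields_positive_slope(self, subject_factory):
        log = subject_factory(w1=0.1, sigma=0.02, schedule_seed=80, agent_seed=81)
        res = model_free_feedback_effect(log)
        assert res["defined"]
        assert res["coefficient"] > 0

    def test_null_weight_yields_near_zero_slope(self, subject_factory):
        log = subject_factory(w1=0.0, sigma=0.001, schedule_seed=82, agent_seed=83)
        res = model_free_feedback_effect(log)
        assert res["defined"]
        assert res["coefficient"] == pytest.approx(0.0, abs=0.01)

    def test_all_approval_is_flagged_undefined(self, default_design):
        from dataclasses import replace
        from selfworth import make_schedule
        from selfworth.cohort import simulate_subject

        design = replace(default_design, group_probs=(1.0, 1.0, 1.0, 1.0))
        cp = ChoiceParams(eta=0.05, beta=8.0, v0_hi=0.8, v0_lo=0.2)
        sp = SelfWorthParams(w0=0.7, w1=0.05, gamma=0.5, sigma=0.05)
        log = simulate_subject(cp, sp, make_schedule(design, 1), 2)
        res = model_free_feedback_effect(log)
        assert not res["defined"]
        assert np.isnan(res["coefficient"])

    def test_too_few_probes_rejected(self, subject_factory):
        log = subject_factory(schedule_seed=84, agent_seed=85)
        probe_idx = np.flatnonzero(log.probe)
        log.probe[probe_idx[4:]] = False
        log.rating[probe_idx[4:]] = np.nan
        with pytest.raises(ValueError, match="at least 5"):
            model_free_feedback_effect(log)
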