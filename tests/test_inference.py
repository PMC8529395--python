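"""Likelihood replay, priors, MAP fitting and BIC comparison."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import prosorl as P
from prosorl.inference import (
    DEFAULT_PRIORS,
    PriorSpec,
    _replay_loglik,
    _replay_loglik_fast,
    _to_arrays,
    bic,
    compare_models,
    fit_map,
    log_likelihood,
    log_posterior,
)
from prosorl.model import RLParams, Variant, replay


class TestLogLikelihood:
    def test_beta_zero_gives_uniform_choice(self, learner_frame):
        n = int((~learner_frame.missed).sum())
        ll = log_likelihood(learner_frame, RLParams.one(0.42, 0.0))
        assert ll == pytest.approx(n * math.log(0.5), rel=1e-12)

    @pytest.mark.parametrize("alpha,beta", [(0.1, 1.0), (0.9, -7.0)])
    def test_single_trial_symmetric_start(self, hand_sequence, alpha, beta):
        one = hand_sequence.iloc[[0]]
        assert log_likelihood(one, RLParams.one(alpha, beta)) == pytest.approx(math.log(0.5))

    def test_matches_hand_replay(self, hand_sequence):
        # step-by-step arithmetic of the three-trial sequence (conftest docstring)
        expected = (
            math.log(0.5)
            + math.log(1.0 / (1.0 + math.exp(-0.6)))
            + math.log(1.0 - 1.0 / (1.0 + math.exp(0.18)))
        )
        ll = log_likelihood(hand_sequence, RLParams.one(0.3, 2.0))
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_kernel_agrees_with_python_reference(self, learner_frame):
        """The compiled likelihood kernel must match both the uncompiled
        function and the independent trajectory replay."""
        for params in [RLParams.one(0.3, 5.0), RLParams.two(0.7, 0.1, -2.0)]:
            for cond in P.Condition:
                sub = learner_frame[learner_frame.condition == cond.value]
                block, chosen, outcome = _to_arrays(sub)
                gain, loss = params.rates
                fast = _replay_loglik_fast(block, chosen, outcome, gain, loss, params.beta, 0.0, 1.0)
                slow = _replay_loglik(block, chosen, outcome, gain, loss, params.beta, 0.0, 1.0)
                ref = float(np.log(replay(sub, params).choice_prob).sum())
                assert fast == pytest.approx(slow, rel=1e-12)
                assert fast == pytest.approx(ref, rel=1e-10)

    def test_empty_sequence_warns_and_returns_zero(self, hand_sequence):
        empty = hand_sequence.iloc[0:0]
        with pytest.warns(UserWarning, match="prior-only"):
            assert log_likelihood(empty, RLParams.one(0.3, 2.0)) == 0.0

    def test_missed_trials_excluded(self, hand_sequence):
        with_miss = hand_sequence.copy()
        extra = hand_sequence.iloc[[0]].assign(
            trial_in_block=3, missed=True, chosen_good=pd.NA, outcome=pd.NA
        )
        with_miss = pd.concat([with_miss, extra], ignore_index=True)
        p = RLParams.one(0.3, 2.0)
        assert log_likelihood(with_miss, p) == pytest.approx(log_likelihood(hand_sequence, p))


class TestPriors:
    def test_beta_density_matches_scipy(self):
        priors = DEFAULT_PRIORS
        for a in [0.1, 0.5, 0.93]:
            assert priors.alpha_logpdf(a) == pytest.approx(
                stats.beta.logpdf(a, 1.2, 1.2), rel=1e-12
            )
        assert priors.alpha_logpdf(-0.1) == -math.inf
        assert priors.alpha_logpdf(1.0) == -math.inf

    def test_gaussian_density_matches_scipy(self):
        priors = DEFAULT_PRIORS
        for b in [-30.0, 0.0, 4.5]:
            assert priors.beta_logpdf(b) == pytest.approx(
                stats.norm.logpdf(b, 0.0, 10.0), rel=1e-12
            )

    def test_flat_alpha_prior_contributes_only_gaussian(self, hand_sequence):
        priors = PriorSpec(alpha_prior=(1.0, 1.0), beta_prior=(0.0, 10.0))
        p = RLParams.one(0.37, 2.0)
        gap = log_posterior(hand_sequence, p, priors) - log_likelihood(hand_sequence, p)
        assert gap == pytest.approx(stats.norm.logpdf(2.0, 0.0, 10.0), rel=1e-12)

    def test_prior_mode_is_half(self):
        assert DEFAULT_PRIORS.alpha_mode == pytest.approx(0.5)
        assert DEFAULT_PRIORS.beta_mode == 0.0

    def test_two_alpha_prior_counts_both_rates(self, hand_sequence):
        p2 = RLParams.two(0.3, 0.6, 2.0)
        gap = log_posterior(hand_sequence, p2) - log_likelihood(hand_sequence, p2)
        expected = (
            DEFAULT_PRIORS.alpha_logpdf(0.3)
            + DEFAULT_PRIORS.alpha_logpdf(0.6)
            + DEFAULT_PRIORS.beta_logpdf(2.0)
        )
        assert gap == pytest.approx(expected, rel=1e-10)


class TestBic:
    def test_hand_value(self):
        assert bic(48 * math.log(0.5), 2, 48) == pytest.approx(74.28, abs=5e-3)

    def test_no_penalty_without_parameters(self):
        assert bic(-10.0, 0, 48) == 20.0

    def test_penalty_linear_in_k(self):
        assert bic(-10.0, 4, 48) - bic(-10.0, 2, 48) == pytest.approx(2 * math.log(48))

    def test_zero_trials_raise(self):
        with pytest.raises(ValueError):
            bic(-1.0, 2, 0)


class TestFitMap:
    def test_zero_trial_fit_returns_prior_modes(self, hand_sequence):
        empty = hand_sequence.iloc[0:0]
        with pytest.warns(UserWarning):
            fit = fit_map(empty, Variant.ONE_ALPHA, seed=1)
        assert fit.params.alpha == pytest.approx(0.5)
        assert fit.params.beta == pytest.approx(0.0)
        assert fit.prior_only and math.isnan(fit.bic)

    def test_bic_identity_and_bounds(self, learner_frame):
        fit = fit_map(learner_frame, Variant.ONE_ALPHA, seed=2, condition=P.Condition.SELF)
        assert fit.loglik <= 0
        assert fit.bic == pytest.approx(bic(fit.loglik, fit.k, fit.n_trials), rel=1e-12)
        assert fit.k == 2 and fit.n_trials == 48
        two = fit_map(learner_frame, Variant.TWO_ALPHA, seed=2, condition=P.Condition.SELF)
        assert two.k == 3

    def test_optimum_dominates_generating_parameters(self, config, learner_frame):
        truth = RLParams.one(0.3, 5.0)
        for cond in P.Condition:
            sub = learner_frame[learner_frame.condition == cond.value]
            fit = fit_map(sub, Variant.ONE_ALPHA, seed=3)
            assert fit.logpost >= log_posterior(sub, truth) - 1e-6

    def test_large_sample_consistency(self):
        """4,800 trials per condition pin alpha to +-0.05 and beta to +-15%."""
        cfg = P.TaskConfig(blocks_per_condition_per_run=100)
        sess = P.generate_session(cfg, seed=41)
        truth = RLParams.one(0.3, 5.0)
        frame = P.simulate_choices(sess, truth, cfg, seed=42).to_frame()
        fit = fit_map(frame, Variant.ONE_ALPHA, seed=43, condition=P.Condition.SELF)
        assert fit.n_trials == 4800
        assert abs(fit.params.alpha - 0.3) <= 0.05
        assert abs(fit.params.beta - 5.0) <= 0.15 * 5.0

    def test_flat_prior_map_equals_mle_grid(self):
        """With flat-ish priors the MAP point coincides with the maximum
        likelihood found by an exhaustive coarse grid (within one step).
        Uses 480 trials so the unregularized optimum is interior (at 48
        trials the flat-prior likelihood can ridge off to extreme beta,
        which is exactly why the MAP priors exist)."""
        cfg = P.TaskConfig(blocks_per_condition_per_run=10)
        sess = P.generate_session(cfg, seed=55)
        frame = P.simulate_choices(sess, RLParams.one(0.5, 3.0), cfg, seed=56).to_frame()
        sub = frame[frame.condition == "self"]
        flat = PriorSpec(alpha_prior=(1.0, 1.0), beta_prior=(0.0, 1e6))
        fit = fit_map(sub, Variant.ONE_ALPHA, priors=flat, seed=5)
        alphas = np.linspace(0.005, 0.995, 100)
        betas = np.linspace(-12, 12, 121)
        block, chosen, outcome = _to_arrays(sub)
        grid = np.array(
            [
                [_replay_loglik(block, chosen, outcome, a, a, b, 0.0, 1.0) for b in betas]
                for a in alphas
            ]
        )
        ia, ib = np.unravel_index(np.argmax(grid), grid.shape)
        assert abs(fit.params.alpha - alphas[ia]) <= alphas[1] - alphas[0] + 1e-9
        assert abs(fit.params.beta - betas[ib]) <= betas[1] - betas[0] + 1e-9

    def test_shrinkage_toward_prior_location(self, learner_frame):
        sub = learner_frame[learner_frame.condition == "self"]
        fitted = []
        for scale in [10.0, 1.0, 0.1]:
            priors = PriorSpec(beta_prior=(0.0, scale))
            fitted.append(abs(fit_map(sub, Variant.ONE_ALPHA, priors=priors, seed=6).params.beta))
        assert fitted[0] > fitted[1] > fitted[2]
        assert fitted[2] < 0.5  # nearly pinned to the prior location

    def test_seeded_determinism(self, learner_frame):
        a = fit_map(learner_frame, Variant.ONE_ALPHA, seed=7, condition=P.Condition.SELF)
        b = fit_map(learner_frame, Variant.ONE_ALPHA, seed=7, condition=P.Condition.SELF)
        assert a == b


class TestCompareModels:
    def test_report_consistency_and_determinism(self, small_cohort_table):
        rep1 = compare_models(small_cohort_table, seed=8, n_starts=5)
        rep2 = compare_models(small_cohort_table, seed=8, n_starts=5)
        pd.testing.assert_frame_equal(rep1.per_fit, rep2.per_fit)
        assert rep1.fraction_one_alpha == rep2.fraction_one_alpha
        pf = rep1.per_fit
        assert len(pf) == 8 * 3
        assert np.allclose(pf.delta_bic, pf.bic_one - pf.bic_two)
        # preference rule: ties and wins for the simpler model
        pref_one = pf.bic_one <= pf.bic_two
        assert (pf.preferred[pref_one] == "one_alpha").all()
        assert (pf.preferred[~pref_one] == "two_alpha").all()
        for cond, frac in rep1.fraction_one_alpha.items():
            sub = pf[pf.condition == cond]
            assert frac == pytest.approx((sub.preferred == "one_alpha").mean())
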