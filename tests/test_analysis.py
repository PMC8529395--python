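"""Learning curves, above-chance tests, partial Spearman, age trends."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import prosorl as P
from prosorl.analysis import (
    above_chance_test,
    age_trend,
    learning_curves,
    partial_spearman,
    performance_summary,
)


def _toy_table():
    """Two agents, one 4-trial block each, hand-countable."""
    rows = []
    pattern = {"a1": [True, False, True, True], "a2": [False, False, True, True]}
    for agent, choices in pattern.items():
        for k, c in enumerate(choices):
            rows.append(
                {
                    "agent_id": agent,
                    "run": 0,
                    "block": 0,
                    "condition": "self",
                    "trial_in_block": k,
                    "pair_id": "p0",
                    "chosen_good": c,
                    "outcome": 1 if c else -1,
                    "missed": False,
                }
            )
    return pd.DataFrame(rows)


class TestLearningCurves:
    def test_hand_counts(self):
        curve = learning_curves(_toy_table())
        frac = curve.set_index("trial_in_block").fraction_correct
        # position-wise means over the two agents: (1+0)/2, 0, 1, 1
        assert list(frac[[0, 1, 2, 3]]) == pytest.approx([0.5, 0.0, 1.0, 1.0])
        assert (curve.n == 2).all()

    def test_all_correct_input(self):
        table = _toy_table().assign(chosen_good=True)
        assert (learning_curves(table).fraction_correct == 1.0).all()

    def test_beta_zero_cohort_flat_at_chance(self, config):
        params = P.RLParams.one(0.5, 0.0)
        frames = []
        for s in range(30):
            sess = P.generate_session(config, seed=900 + s, agent_id=f"a{s}")
            frames.append(P.simulate_choices(sess, params, config, seed=950 + s).to_frame())
        curve = learning_curves(pd.concat(frames, ignore_index=True))
        assert np.allclose(curve.fraction_correct, 0.5, atol=0.12)
        assert abs(curve.fraction_correct.mean() - 0.5) < 0.03

    def test_strong_learners_rise_after_early_trials(self, config):
        params = P.RLParams.one(0.5, 8.0)
        frames = []
        for s in range(40):
            sess = P.generate_session(config, seed=700 + s, agent_id=f"a{s}")
            frames.append(P.simulate_choices(sess, params, config, seed=750 + s).to_frame())
        curve = learning_curves(pd.concat(frames, ignore_index=True))
        pooled = curve.groupby("trial_in_block").fraction_correct.mean()
        smoothed = pooled.rolling(3, min_periods=1).mean()
        assert (smoothed.diff().dropna()[3:] > -0.05).all()
        assert pooled[12:].mean() > pooled[:4].mean() + 0.1

    def test_missed_trials_excluded(self):
        table = _toy_table()
        table["chosen_good"] = table["chosen_good"].astype("boolean")
        table["outcome"] = table["outcome"].astype("Int64")
        table.loc[0, "chosen_good"] = pd.NA
        table.loc[0, "outcome"] = pd.NA
        table.loc[0, "missed"] = True
        curve = learning_curves(table)
        frac0 = curve[curve.trial_in_block == 0]
        assert frac0.n.iloc[0] == 1 and frac0.fraction_correct.iloc[0] == 0.0


class TestPerformanceSummary:
    def test_fraction_over_non_missed(self):
        out = performance_summary(_toy_table())
        by_agent = out.set_index("agent_id").fraction_correct
        assert by_agent["a1"] == pytest.approx(0.75)
        assert by_agent["a2"] == pytest.approx(0.5)


class TestAboveChance:
    def test_df_is_n_minus_one(self):
        rng = np.random.default_rng(1)
        res = above_chance_test(rng.uniform(0.5, 0.9, size=74))
        assert res.df == 73

    def test_exact_chance_sample(self):
        res = above_chance_test([0.5] * 5)
        assert res.t == 0.0 and res.zero_variance

    def test_matches_textbook_formula(self):
        x = np.array([0.55, 0.62, 0.58, 0.71, 0.49])
        res = above_chance_test(x)
        t_hand = (x.mean() - 0.5) / (x.std(ddof=1) / np.sqrt(5))
        assert res.t == pytest.approx(t_hand, rel=1e-12)
        assert res.p == pytest.approx(2 * stats.t.sf(abs(t_hand), 4), rel=1e-12)

    def test_zero_variance_off_chance_flags_infinite_t(self):
        res = above_chance_test([0.8] * 6)
        assert np.isinf(res.t) and res.zero_variance and res.p == 0.0


@pytest.fixture(scope="module")
def fixture8():
    rng = np.random.default_rng(44)
    z = rng.normal(size=8)
    x = z + rng.normal(scale=0.5, size=8)
    y = -z + rng.normal(scale=0.5, size=8)
    return x, y, z


class TestPartialSpearman:

    def test_no_covariates_reduces_to_spearman(self, fixture8):
        x, y, _ = fixture8
        rho, p = partial_spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, rel=1e-12)

    def test_matches_residualization_oracle(self, fixture8):
        """Brute-force oracle: rank everything, regress x- and y-ranks on
        covariate ranks via polyfit, Pearson-correlate the residuals."""
        x, y, z = fixture8
        rho, _ = partial_spearman(x, y, [z])
        rx, ry, rz = (stats.rankdata(v) for v in (x, y, z))
        res_x = rx - np.polyval(np.polyfit(rz, rx, 1), rz)
        res_y = ry - np.polyval(np.polyfit(rz, ry, 1), rz)
        oracle = np.corrcoef(res_x, res_y)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-10)

    def test_matches_pingouin(self, fixture8):
        pingouin = pytest.importorskip("pingouin")
        x, y, z = fixture8
        frame = pd.DataFrame({"x": x, "y": y, "z": z})
        ref = pingouin.partial_corr(frame, x="x", y="y", covar="z", method="spearman")
        rho, p = partial_spearman(x, y, [z])
        assert rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        pcol = "p_val" if "p_val" in ref.columns else "p-val"
        assert p == pytest.approx(float(ref[pcol].iloc[0]), abs=1e-8)

    def test_symmetry(self, fixture8):
        x, y, z = fixture8
        assert partial_spearman(x, y, [z])[0] == pytest.approx(
            partial_spearman(y, x, [z])[0], abs=1e-12
        )

    @given(st.integers(min_value=0, max_value=1_000))
    @settings(max_examples=15, deadline=None)
    def test_invariant_to_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x, y, z = rng.normal(size=(3, 12))
        base, _ = partial_spearman(x, y, [z])
        trans, _ = partial_spearman(np.exp(x), 2 * y + 5, [z**3])
        assert base == pytest.approx(trans, abs=1e-10)

    def test_perfectly_explained_variable_flagged(self, fixture8):
        x, _, z = fixture8
        with pytest.warns(UserWarning, match="degenerate"):
            rho, p = partial_spearman(x, z, [z])
        assert rho == 0.0 and p == 1.0

    def test_constant_covariate_rejected(self, fixture8):
        x, y, _ = fixture8
        with pytest.raises(ValueError, match="constant"):
            partial_spearman(x, y, [np.ones(8)])


class TestAgeTrend:
    def test_perfect_linear_relation(self):
        ages = np.linspace(9, 21, 20)
        res = age_trend(2 * ages + 1, ages)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.spearman_rho == pytest.approx(1.0)

    def test_independent_quantity_near_zero(self):
        rng = np.random.default_rng(9)
        ages = rng.uniform(9, 21, size=1_000)
        res = age_trend(rng.normal(size=1_000), ages)
        assert abs(res.pearson_r) < 0.1

    def test_constant_input_flagged(self):
        with pytest.warns(UserWarning):
            res = age_trend([1.0] * 6, np.arange(6))
        assert np.isnan(res.pearson_r)

    def test_recovers_generator_alpha_age_link(self, config, small_cohort_table):
        fits = P.fit_cohort(
            small_cohort_table,
            P.Variant.ONE_ALPHA,
            seed=2,
            n_starts=5,
            conditions=[P.Condition.OTHER],
        )
        ages = small_cohort_table.drop_duplicates("agent_id").set_index("agent_id").age
        res = age_trend(fits.alpha.to_numpy(), ages.loc[fits.agent_id].to_numpy())
        assert res.spearman_rho < 0
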