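import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from crossmap.analysis import (
    LOGISTIC_RESIDUAL_VARIANCE,
    apply_exclusions,
    build_design,
    condition_summary,
    fit_glmm,
    likelihood_ratio_test,
    r2_nakagawa,
    zero_min_transform,
)
from crossmap.glmm import MixedLogit
from crossmap.item_selection import CONDITIONS
from crossmap.synthetic import ChoiceModelConfig, simulate_trials


def trial_table(participants):
    """Hand-built trial table: {pid: (n_catch_correct, responses)}."""
    rows = []
    for pid, (n_correct, resp) in participants.items():
        for j, r in enumerate(resp):
            rows.append(
                {
                    "participant_id": pid,
                    "word": f"w{j}",
                    "chose_model_image": r,
                    "is_catch": 0,
                    "catch_correct": np.nan,
                }
            )
        for j in range(10):
            rows.append(
                {
                    "participant_id": pid,
                    "word": f"catch{j}",
                    "chose_model_image": np.nan,
                    "is_catch": 1,
                    "catch_correct": 1 if j < n_correct else 0,
                }
            )
    return pd.DataFrame(rows)


class TestApplyExclusions:
    def test_seven_of_ten_dropped_ten_retained(self):
        trials = trial_table({"p1": (7, [1, 0]), "p2": (10, [1, 1])})
        clean, log = apply_exclusions(trials)
        assert set(clean["participant_id"]) == {"p2"}
        assert not clean["is_catch"].astype(bool).any()
        assert log.set_index("participant_id").loc["p1", "excluded"]

    def test_boundary_eight_retained(self):
        trials = trial_table({"p1": (8, [1])})
        clean, _ = apply_exclusions(trials)
        assert set(clean["participant_id"]) == {"p1"}

    def test_three_participant_hand_count(self):
        trials = trial_table({"a": (5, [1, 1]), "b": (9, [0, 1]), "c": (8, [1, 0])})
        clean, log = apply_exclusions(trials)
        assert set(clean["participant_id"]) == {"b", "c"}
        assert len(clean) == 4
        assert int(log["excluded"].sum()) == 1

    def test_participant_without_catch_trials_rejected(self):
        trials = trial_table({"p1": (10, [1])})
        extra = pd.DataFrame(
            [{"participant_id": "p2", "word": "w0", "chose_model_image": 1,
              "is_catch": 0, "catch_correct": np.nan}]
        )
        with pytest.raises(ValueError, match="p2"):
            apply_exclusions(pd.concat([trials, extra], ignore_index=True))


class TestZeroMinTransform:
    def test_shift(self):
        df = pd.DataFrame({"x": [2.0, 3.0, 5.0]})
        out, minima = zero_min_transform(df, ["x"])
        assert list(out["x"]) == [0.0, 1.0, 3.0]
        assert minima == {"x": 2.0}

    def test_idempotent_when_already_zero(self):
        df = pd.DataFrame({"x": [0.0, 1.0, 3.0]})
        out, _ = zero_min_transform(df, ["x"])
        assert list(out["x"]) == [0.0, 1.0, 3.0]

    def test_slope_invariant_intercept_shifts(self, rng):
        # reparameterisation: slope unchanged, intercept absorbs the shift
        items = pd.DataFrame(
            {
                "word": [f"w{i}" for i in range(40)],
                "concreteness": rng.uniform(2, 5, 40),
                "mean_training_similarity": rng.uniform(0.1, 0.3, 40),
            }
        )
        cfg = ChoiceModelConfig(
            beta0=-1.0, beta_concreteness=0.5, beta_neighbor=0.0,
            tau_participant=0.3, tau_item=0.3, n_participants=25,
            n_catch=0, seed=7,
        )
        trials = simulate_trials(items, cfg)
        shifted, minima = zero_min_transform(
            trials, ["concreteness", "mean_training_similarity"]
        )
        f_raw = fit_glmm(trials, design="exp3", terms=["concreteness"])
        f_shift = fit_glmm(shifted, design="exp3", terms=["concreteness"])
        assert f_shift.params["concreteness"] == pytest.approx(
            f_raw.params["concreteness"], abs=1e-2
        )
        assert f_shift.params["Intercept"] == pytest.approx(
            f_raw.params["Intercept"] + minima["concreteness"]
            * f_raw.params["concreteness"],
            abs=1e-2,
        )
        # LRT against the intercept-only model is invariant to the shift
        r_raw = fit_glmm(trials, design="exp3", terms=[])
        r_shift = fit_glmm(shifted, design="exp3", terms=[])
        l_raw = likelihood_ratio_test(f_raw, r_raw)
        l_shift = likelihood_ratio_test(f_shift, r_shift)
        assert l_shift.statistic == pytest.approx(l_raw.statistic, abs=0.02)


class TestDesigns:
    @staticmethod
    def all_condition_trials():
        rows = []
        for cond in CONDITIONS:
            rows.append({"participant_id": "p1", "word": cond,
                         "condition": cond, "chose_model_image": 1})
        return pd.DataFrame(rows)

    def test_exp12_full_design_columns(self):
        X, names = build_design(self.all_condition_trials(), "exp12")
        assert names == ["Intercept", "concrete", "near", "maximum", "concrete:near"]
        df = pd.DataFrame(X, columns=names)
        # abstract/far is the reference: first row all zeros beyond intercept
        assert df.iloc[0].tolist() == [1, 0, 0, 0, 0]
        # concrete/near row activates concrete, near and the interaction
        assert df.iloc[3].tolist() == [1, 1, 1, 0, 1]

    def test_exp3_design_columns(self):
        trials = pd.DataFrame(
            {
                "concreteness": [1.0, 2.0],
                "mean_training_similarity": [0.1, 0.2],
            }
        )
        X, names = build_design(trials, "exp3")
        assert names[-1] == "concreteness:similarity"
        np.testing.assert_allclose(X[:, 3], [0.1, 0.4])


class TestFitGlmm:
    def test_intercept_only_matches_logit_of_proportion(self):
        rng = np.random.default_rng(3)
        rows = []
        for p in range(12):
            for i in range(30):
                rows.append(
                    {
                        "participant_id": f"p{p}",
                        "word": f"w{i}",
                        "condition": "abstract/far",
                        "chose_model_image": int(rng.random() < 0.7),
                    }
                )
        trials = pd.DataFrame(rows)
        res = fit_glmm(trials, design="exp12", terms=[])
        prop = trials["chose_model_image"].mean()
        assert res.params["Intercept"] == pytest.approx(logit(prop), abs=0.05)


class TestLikelihoodRatio:
    def test_identical_models_give_zero_stat_p_one(self, rng):
        y = rng.integers(0, 2, 200).astype(float)
        X = np.ones((200, 1))
        part = np.repeat(np.arange(10), 20)
        item = np.tile(np.arange(20), 10)
        res = MixedLogit(y, X, {"p": part, "i": item}).fit()
        l = likelihood_ratio_test(res, res)
        assert l.statistic == 0.0
        assert l.pvalue == pytest.approx(1.0)

    def test_df_counts_dropped_categorical_levels(self):
        rng = np.random.default_rng(4)
        items = pd.DataFrame(
            {"word": [f"{c}#{j}" for c in CONDITIONS for j in range(8)],
             "condition": [c for c in CONDITIONS for j in range(8)]}
        )
        cfg = ChoiceModelConfig(
            beta0=0.3, beta_concreteness=0.0, beta_neighbor=0.0,
            tau_participant=0.3, tau_item=0.3, n_participants=10,
            n_catch=0, seed=8,
        )
        trials = simulate_trials(items, cfg)
        full = fit_glmm(trials, terms=["concreteness", "neighbors"])
        no_neigh = fit_glmm(trials, terms=["concreteness"])
        l = likelihood_ratio_test(full, no_neigh)
        assert l.df == 2  # near + maximum dummies

    def test_non_nested_rejected(self, rng):
        y = rng.integers(0, 2, 100).astype(float)
        part = np.repeat(np.arange(10), 10)
        item = np.tile(np.arange(10), 10)
        x = rng.standard_normal(100)
        a = MixedLogit(y, np.column_stack([np.ones(100), x]),
                       {"p": part, "i": item}, ["Intercept", "a"]).fit()
        b = MixedLogit(y, np.column_stack([np.ones(100), -x]),
                       {"p": part, "i": item}, ["Intercept", "b"]).fit()
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(a, b)


class TestR2Nakagawa:
    class HandFit:
        def __init__(self, params, vc, exog):
            self.params = params
            self.random_variances = vc
            self.model = type("M", (), {"exog": exog})()

    def test_closed_form(self):
        # var(fixed predictor) = 1, total random variance = 2
        n = 1000
        x = np.linspace(-np.sqrt(3), np.sqrt(3), n)  # variance 1 (population)
        exog = np.column_stack([np.ones(n), x])
        fit = self.HandFit(np.array([0.0, 1.0]), {"p": 1.2, "i": 0.8}, exog)
        marg, cond = r2_nakagawa(fit)
        denom = np.var(x) + 2.0 + LOGISTIC_RESIDUAL_VARIANCE
        assert marg == pytest.approx(np.var(x) / denom, abs=1e-12)
        assert cond == pytest.approx((np.var(x) + 2.0) / denom, abs=1e-12)

    def test_intercept_only_marginal_zero(self):
        exog = np.ones((50, 1))
        fit = self.HandFit(np.array([0.7]), {"p": 0.5}, exog)
        marg, cond = r2_nakagawa(fit)
        assert marg == pytest.approx(0.0, abs=1e-12)
        assert cond == pytest.approx(0.5 / (0.5 + LOGISTIC_RESIDUAL_VARIANCE))

    def test_zero_random_variance_equates_both(self, rng):
        exog = np.column_stack([np.ones(100), rng.standard_normal(100)])
        fit = self.HandFit(np.array([0.1, 0.4]), {"p": 0.0, "i": 0.0}, exog)
        marg, cond = r2_nakagawa(fit)
        assert marg == pytest.approx(cond)


class TestConditionSummary:
    def test_saturated_condition(self):
        trials = pd.DataFrame(
            {"condition": ["a"] * 5, "chose_model_image": [1] * 5}
        )
        s = condition_summary(trials)
        assert s.loc[0, "performance"] == 1.0

    def test_wald_interval_closed_form(self):
        trials = pd.DataFrame(
            {"condition": ["a"] * 100, "chose_model_image": [1] * 50 + [0] * 50}
        )
        s = condition_summary(trials)
        assert s.loc[0, "performance"] == pytest.approx(0.5)
        assert s.loc[0, "ci_lower"] == pytest.approx(0.402, abs=0.001)
        assert s.loc[0, "ci_upper"] == pytest.approx(0.598, abs=0.001)

    def test_row_order_invariance(self, rng):
        trials = pd.DataFrame(
            {
                "condition": rng.choice(["a", "b"], 60),
                "chose_model_image": rng.integers(0, 2, 60),
            }
        )
        s1 = condition_summary(trials)
        s2 = condition_summary(trials.sample(frac=1, random_state=0))
        pd.testing.assert_frame_equal(s1, s2)
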