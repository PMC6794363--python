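"""Inference: cleaning, screening, regressions, moderation, descriptives."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dietchoice as dc
from conftest import normal_equations
from dietchoice.inference import (
    ModelResult,
    assign_weight_status,
    clean_participants,
    describe_by_weight_status,
    fit_outcome_models,
    fit_rt_models,
    moderation_analysis,
    screen_covariates,
    span_effect,
)


def demo_frame(n, rng=None, height=1.75, weight=70.0):
    rng = rng or np.random.default_rng(0)
    return pd.DataFrame(
        {
            "participant_id": np.arange(1, n + 1),
            "age": rng.uniform(18, 50, n).round(1),
            "sex": rng.choice(["male", "female"], n),
            "height_m": np.full(n, height),
            "weight_kg": np.full(n, weight),
            "race": rng.choice(["White", "Other"], n, p=[0.8, 0.2]),
            "income_usd": rng.uniform(2e4, 9e4, n).round(),
        }
    )


def varied_trials(pids, rng=None):
    rng = rng or np.random.default_rng(1)
    rows = []
    for pid in pids:
        rows.append(pd.DataFrame(
            {"participant_id": pid, "target_item_id": np.arange(2, 12),
             "referent_item_id": 1,
             "preference": rng.integers(-2, 3, size=10),
             "rt_ms": rng.uniform(800, 2000, size=10)}))
    return pd.concat(rows, ignore_index=True)


class TestWeightStatus:
    @pytest.mark.parametrize("bmi, status", [
        (18.0, "healthy"), (24.9, "healthy"), (25.0, "overweight"),
        (29.9, "overweight"), (30.0, "obese"), (45.0, "obese"),
    ])
    def test_cdc_cut_points(self, bmi, status):
        assert assign_weight_status([bmi]).iloc[0] == status


class TestCleanParticipants:
    def test_five_rule_violators_removed_from_522(self):
        rng = np.random.default_rng(2)
        demo = demo_frame(522, rng)
        # three implausibly short, one implausible BMI, one invariant responder
        demo.loc[demo.index[:3], "height_m"] = 0.40
        demo.loc[demo.index[3], "weight_kg"] = 9.2  # BMI ~3 at 1.75 m
        trials = varied_trials(demo["participant_id"], rng)
        invariant_pid = 522
        trials.loc[trials["participant_id"] == invariant_pid, "preference"] = 2
        ratings = pd.DataFrame(
            {"participant_id": np.repeat(demo["participant_id"], 11),
             "item_id": np.tile(np.arange(1, 12), 522),
             "taste": rng.integers(1, 6, 522 * 11),
             "health": rng.integers(1, 6, 522 * 11)}
        )
        ratings.loc[ratings["participant_id"] == invariant_pid,
                    ["taste", "health"]] = 3
        kept, report = clean_participants(demo, trials, ratings)
        assert len(kept) == 517
        assert sorted(report["rule"]) == ["bmi", "height", "height", "height",
                                          "invariant_responder"]

    def test_plausible_participant_retained_with_bmi(self):
        demo = demo_frame(3)
        trials = varied_trials(demo["participant_id"])
        kept, report = clean_participants(demo, trials)
        assert report.empty
        assert kept["bmi"].iloc[0] == pytest.approx(70 / 1.75**2)  # 22.86
        assert (kept["weight_status"] == "healthy").all()

    def test_varied_raters_with_constant_preference_are_kept(self):
        # constant preference alone is not invariant responding when the
        # ratings vary (the paper's rule targets same-response-to-everything)
        rng = np.random.default_rng(3)
        demo = demo_frame(4, rng)
        trials = varied_trials(demo["participant_id"], rng)
        trials.loc[trials["participant_id"] == 1, "preference"] = 2
        ratings = pd.DataFrame(
            {"participant_id": np.repeat(demo["participant_id"], 11),
             "item_id": np.tile(np.arange(1, 12), 4),
             "taste": rng.integers(1, 6, 44),
             "health": rng.integers(1, 6, 44)}
        )
        kept, report = clean_participants(demo, trials, ratings)
        assert len(kept) == 4

    def test_empty_result_is_hard_error(self):
        demo = demo_frame(2, height=0.3)
        trials = varied_trials(demo["participant_id"])
        with pytest.raises(ValueError, match="no participants"):
            clean_participants(demo, trials)


class TestScreenCovariates:
    def test_outcome_copy_is_selected(self):
        rng = np.random.default_rng(4)
        demo = demo_frame(50, rng)
        outcomes = pd.DataFrame(
            {"participant_id": demo["participant_id"],
             "health_sensitivity": demo["age"].to_numpy()})
        assert "age" in screen_covariates(demo, outcomes)

    def test_null_covariate_selected_at_nominal_rate(self):
        rng = np.random.default_rng(5)
        hits = 0
        reps = 400
        for _ in range(reps):
            n = 60
            demo = pd.DataFrame(
                {"participant_id": np.arange(n),
                 "age": rng.normal(size=n)})
            outcomes = pd.DataFrame(
                {"participant_id": np.arange(n), "y": rng.normal(size=n)})
            hits += "age" in screen_covariates(
                demo, outcomes, demographic_vars=("age",))
        assert hits / reps == pytest.approx(0.10, abs=0.04)

    def test_age_rt_dependence_found_on_synthetic_cohort(self):
        cfg = dc.SimulationConfig(seed=3, n_participants=200,
                                  age_rt_ms_per_year=8.0)
        demo, items, ratings, trials, _ = dc.generate_cohort(cfg)
        mean_rt = (trials.groupby("participant_id")["rt_ms"].mean()
                   .rename("mean_rt_ms").reset_index())
        assert "age" in screen_covariates(demo, mean_rt,
                                          demographic_vars=("age",))

    def test_constant_variable_skipped_with_warning(self, caplog):
        demo = demo_frame(10)
        demo["age"] = 30.0
        outcomes = pd.DataFrame({"participant_id": demo["participant_id"],
                                 "y": np.arange(10.0)})
        with caplog.at_level("WARNING"):
            out = screen_covariates(demo, outcomes, demographic_vars=("age",))
        assert out == []
        assert "constant" in caplog.text


class TestOutcomeModels:
    def _table(self, n=400, beta=0.5, seed=6):
        rng = np.random.default_rng(seed)
        cr = rng.normal(40, 20, n)
        dis = rng.normal(35, 18, n)
        z = (cr - cr.mean()) / cr.std(ddof=1)
        noise_sd = np.sqrt(1 - beta**2)
        df = pd.DataFrame({
            "participant_id": np.arange(n), "cr": cr, "disinhibited": dis,
            "health_sensitivity": beta * z + rng.normal(0, noise_sd, n),
            "taste_sensitivity": rng.normal(size=n),
            "prop_healthy": rng.uniform(0, 1, n),
            "prop_tasty": rng.uniform(0, 1, n),
        })
        return df

    def test_standardized_slope_recovers_generating_beta(self):
        df = self._table(beta=0.5)
        res = fit_outcome_models(df)["health_sensitivity~cr"]
        assert res.coef("cr") == pytest.approx(0.5, abs=0.1)

    def test_null_outcome_slope_near_zero(self):
        df = self._table(beta=0.0, n=1000)
        res = fit_outcome_models(df)["taste_sensitivity~cr"]
        assert abs(res.coef("cr")) < 0.08

    def test_standardized_simple_slope_equals_pearson_r(self):
        df = self._table()
        res = fit_outcome_models(df)["health_sensitivity~cr"]
        r = stats.pearsonr(df["cr"], df["health_sensitivity"])[0]
        assert res.coef("cr") == pytest.approx(r, abs=1e-10)

    def test_all_fits_match_normal_equations(self):
        df = self._table(n=50)
        res = fit_outcome_models(df)["health_sensitivity~adjusted"]
        z = lambda s: (s - s.mean()) / s.std(ddof=1)
        X = np.column_stack([z(df["cr"]), z(df["disinhibited"])])
        b = normal_equations(X, z(df["health_sensitivity"]))
        assert res.coef("cr") == pytest.approx(b[1], abs=1e-8)
        assert res.coef("disinhibited") == pytest.approx(b[2], abs=1e-8)

    def test_ci_consistent_with_estimate_and_se(self):
        df = self._table(n=80)
        res = fit_outcome_models(df)["health_sensitivity~cr"]
        row = res.table.set_index("term").loc["cr"]
        tcrit = stats.t.ppf(0.975, res.n_obs - 2)
        assert row["ci_low"] == pytest.approx(
            row["estimate"] - tcrit * row["se"], abs=1e-8)
        assert 0.0 <= row["p"] <= 1.0


class TestRTModels:
    def test_known_slopes_recovered_within_ci(self):
        # homogeneous slopes (no trait modulation): the joint trial-level
        # model must recover the generating -13 / -11 ms per unit
        cfg = dc.SimulationConfig(seed=8, rt_trait_modulation=0.0,
                                  outlier_rate=0.0)
        demo, items, ratings, trials, _ = dc.generate_cohort(cfg)
        scores = dc.score_tfeq(items)
        derived = dc.derive_trials(trials, ratings)
        trimmed, _ = dc.filter_rt_outliers(derived)
        res = dc.fit_rt_models(trimmed, scores)["rt~health_diff+taste_diff"]
        t = res.table.set_index("term")
        assert (t.loc["health_diff", "ci_low"] <= -13.0
                <= t.loc["health_diff", "ci_high"])
        assert (t.loc["taste_diff", "ci_low"] <= -11.0
                <= t.loc["taste_diff", "ci_high"])

    def test_rt_independent_of_differences_gives_null_slopes(self):
        rng = np.random.default_rng(9)
        n = 4000
        derived = pd.DataFrame(
            {"participant_id": rng.integers(1, 50, n),
             "health_diff": rng.integers(-4, 5, n).astype(float),
             "taste_diff": rng.integers(-4, 5, n).astype(float),
             "rt_ms": rng.normal(1300, 200, n)})
        scores = pd.DataFrame(
            {"participant_id": np.arange(1, 50),
             "cr": rng.normal(40, 20, 49),
             "disinhibited": rng.normal(35, 18, 49)})
        res = dc.fit_rt_models(derived, scores)
        assert abs(res["rt~health_diff"].coef("health_diff")) < 5
        assert res["rt~health_diff"].pvalue("health_diff") > 0.01

    def test_cluster_robust_flag_changes_se_not_estimate(self, cohort_trimmed,
                                                         cohort_scores):
        trimmed, _ = cohort_trimmed
        plain = dc.fit_rt_models(trimmed, cohort_scores)["rt~health_diff"]
        robust = dc.fit_rt_models(trimmed, cohort_scores,
                                  cluster_robust=True)["rt~health_diff"]
        assert robust.coef("health_diff") == pytest.approx(
            plain.coef("health_diff"), abs=1e-8)
        assert robust.table.set_index("term").loc["health_diff", "se"] != \
            plain.table.set_index("term").loc["health_diff", "se"]


class TestModeration:
    def test_generator_moderation_detected(self, cohort_trimmed, cohort_scores):
        trimmed, _ = cohort_trimmed
        res = moderation_analysis(trimmed, cohort_scores, moderator="cr",
                                  difference_kind="health")
        assert res.slope("high") < res.slope("low")
        assert res.significant

    def test_continuous_form_agrees_in_sign(self, cohort_trimmed, cohort_scores):
        trimmed, _ = cohort_trimmed
        res = moderation_analysis(trimmed, cohort_scores, moderator="cr",
                                  difference_kind="health", form="continuous")
        assert res.interaction_estimate < 0
        assert res.interaction_p < 0.10

    def test_median_split_ties_go_low(self):
        rng = np.random.default_rng(10)
        scores = pd.DataFrame({"participant_id": np.arange(1, 6),
                               "cr": [10.0, 20.0, 30.0, 40.0, 50.0]})
        derived = pd.DataFrame(
            {"participant_id": np.repeat(np.arange(1, 6), 20),
             "health_diff": rng.integers(-4, 5, 100).astype(float),
             "rt_ms": rng.normal(1300, 100, 100)})
        res = moderation_analysis(derived, scores, moderator="cr",
                                  difference_kind="health")
        # median cr = 30 -> participants 1-3 low, 4-5 high
        assert res.strata["low"].n_obs == 60
        assert res.strata["high"].n_obs == 40

    def test_binary_moderator_matches_median_split(self):
        # when the moderator is already binary, the continuous z-scored
        # interaction is the same linear hypothesis as the median split
        rng = np.random.default_rng(11)
        n_part = 80
        scores = pd.DataFrame(
            {"participant_id": np.arange(1, n_part + 1),
             "cr": np.r_[np.zeros(n_part // 2), np.ones(n_part // 2)] * 50})
        derived = pd.DataFrame(
            {"participant_id": np.repeat(np.arange(1, n_part + 1), 30),
             "health_diff": rng.integers(-4, 5, n_part * 30).astype(float),
             "rt_ms": rng.normal(1300, 150, n_part * 30)})
        split = moderation_analysis(derived, scores, moderator="cr",
                                    difference_kind="health")
        cont = moderation_analysis(derived, scores, moderator="cr",
                                   difference_kind="health", form="continuous")
        assert cont.interaction_p == pytest.approx(split.interaction_p,
                                                   abs=1e-9)

    def test_empty_stratum_is_hard_error(self):
        scores = pd.DataFrame({"participant_id": [1, 2], "cr": [10.0, 10.0]})
        derived = pd.DataFrame(
            {"participant_id": [1, 1, 2, 2],
             "health_diff": [1.0, -1.0, 2.0, -2.0],
             "rt_ms": [1000.0, 1100.0, 1200.0, 1300.0]})
        with pytest.raises(ValueError, match="empty"):
            moderation_analysis(derived, scores, moderator="cr",
                                difference_kind="health")


class TestDescriptives:
    def _demo_scores(self, n=300, seed=12):
        rng = np.random.default_rng(seed)
        demo = demo_frame(n, rng)
        demo["bmi"] = rng.uniform(18, 40, n)
        demo["weight_status"] = assign_weight_status(demo["bmi"]).to_numpy()
        scores = pd.DataFrame(
            {"participant_id": demo["participant_id"],
             "cr": rng.normal(40, 20, n), "ue": rng.normal(35, 18, n),
             "ee": rng.normal(35, 25, n)})
        return demo, scores

    def test_identical_groups_not_significant(self):
        demo, scores = self._demo_scores()
        out = describe_by_weight_status(demo, scores)
        cont = out[out["kind"] == "continuous"]
        assert (cont["p"] > 0.01).all()

    def test_anova_equals_squared_t_for_two_groups(self):
        rng = np.random.default_rng(13)
        demo = demo_frame(200, rng)
        demo["bmi"] = np.r_[np.full(100, 22.0), np.full(100, 27.0)]
        demo["weight_status"] = assign_weight_status(demo["bmi"]).to_numpy()
        age = np.r_[rng.normal(0, 1, 100), rng.normal(1, 1, 100)]
        demo["age"] = age
        scores = pd.DataFrame({"participant_id": demo["participant_id"],
                               "cr": rng.normal(size=200),
                               "ue": rng.normal(size=200),
                               "ee": rng.normal(size=200)})
        out = describe_by_weight_status(demo, scores).set_index("variable")
        t, p = stats.ttest_ind(age[:100], age[100:])
        assert out.loc["age", "stat"] == pytest.approx(t**2)
        assert out.loc["age", "p"] == pytest.approx(p)
        assert out.loc["age", "p"] < 0.001


class TestSpanEffect:
    @pytest.mark.parametrize("coef, span, expected", [
        (0.0, 8, 0), (-11.67, 8, 93), (-10.0, 4, 40), (12.2, 8, 98),
    ])
    def test_absolute_span_product(self, coef, span, expected):
        assert span_effect(coef, span) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            span_effect(float("nan"), 8)
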