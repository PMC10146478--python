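import numpy as np
import pandas as pd
import pytest

from virtualcontrols.calibration import fit_behavior_weights
from virtualcontrols.norm_model import NormTable
from virtualcontrols.psych_scale import ItemBattery, cronbach_alpha, score_survey
from virtualcontrols.synthetic_data import (
    DEFAULT_ANCHORS,
    NormPoolSpec,
    TrialSpec,
    default_family_table,
    default_true_weights,
    generate_norm_pool,
    generate_trial,
    item_responses_from_psych,
    read_survey,
    write_survey,
)


class TestNormPool:
    def test_flat_noiseless_curve_constant_pool(self):
        anchors = ((10.0, 0.0, 0.0, 7.0), (90.0, 0.0, 0.0, 7.0))
        pool = generate_norm_pool(
            NormPoolSpec(n_records=500, anchors=anchors, noise_sd=0.0, seed=1)
        )
        assert (pool["psych"] == 7.0).all()

    def test_deterministic_given_seed(self):
        p1 = generate_norm_pool(NormPoolSpec(n_records=2_000, seed=42))
        p2 = generate_norm_pool(NormPoolSpec(n_records=2_000, seed=42))
        pd.testing.assert_frame_equal(p1, p2)
        p3 = generate_norm_pool(NormPoolSpec(n_records=2_000, seed=43))
        assert not p1["psych"].equals(p3["psych"])

    def test_crossing_generator_curves_rejected(self):
        anchors = ((10.0, 0.0, 0.0, 9.0), (90.0, 0.0, 0.0, 7.0))  # upper below lower
        with pytest.raises(ValueError, match="cross"):
            NormPoolSpec(n_records=100, anchors=anchors)

    def test_values_respect_invariants(self):
        pool = generate_norm_pool(NormPoolSpec(n_records=5_000, noise_sd=2.0, seed=7))
        assert pool["psych"].between(0, 10).all()
        assert pool["age_months"].between(120, 240).all()

    def test_psych_declines_with_age(self):
        pool = generate_norm_pool(NormPoolSpec(n_records=100_000, seed=3))
        young = pool[pool.age_months < 150]["psych"].mean()
        old = pool[pool.age_months > 210]["psych"].mean()
        assert old < young - 1.0


class TestDefaultFamilyTable:
    def test_anchor_curves_reproduced_on_grid(self, family_table):
        for pct, a, b, c in DEFAULT_ANCHORS:
            if pct in family_table.percentiles:
                expected = np.clip(a * 130.0**2 + b * 130.0 + c, 0, 10)
                assert family_table.eval(pct, 130) == pytest.approx(expected)

    def test_non_crossing_everywhere(self, family_table):
        assert np.all(np.diff(family_table.grid, axis=0) >= 0)

    def test_published_sample_curves_embedded(self, family_table, reference_norms):
        # the 25th/50th family anchors are the published sample curves (the
        # 75th uses a gently declining variant instead of the clamped constant)
        for pct in (25.0, 50.0):
            for age in (120, 144, 200):
                assert family_table.eval(pct, age) == pytest.approx(
                    reference_norms.eval(pct, age), abs=1e-9
                )


class TestItemResponses:
    def test_noiseless_items_equal_psych(self):
        # reliability -> 1 means vanishing item noise
        rng = np.random.default_rng(0)
        psych = rng.uniform(2, 8, 200)
        items = item_responses_from_psych(psych, reliability=0.999999, rng=rng)
        assert np.allclose(items, psych[:, None], atol=0.05)
        alpha = cronbach_alpha(items)
        assert alpha > 0.99

    def test_target_alpha_hit_monte_carlo(self):
        # psych centred mid-scale so clamping is negligible
        rng = np.random.default_rng(1)
        psych = rng.normal(5.0, 0.9, 20_000).clip(0, 10)
        items = item_responses_from_psych(
            psych, reliability=0.681, rng=rng, between_var=float(np.var(psych, ddof=1))
        )
        assert cronbach_alpha(items) == pytest.approx(0.681, abs=0.05)

    def test_recomputed_score_correlates_with_psych(self):
        rng = np.random.default_rng(2)
        psych = rng.normal(5.0, 0.9, 5_000).clip(0, 10)
        items = item_responses_from_psych(psych, reliability=0.85, rng=rng)
        score = items.mean(axis=1)
        assert np.corrcoef(score, psych)[0, 1] > 0.9

    def test_invalid_targets_rejected(self):
        psych = np.full(10, 5.0)
        with pytest.raises(ValueError):
            item_responses_from_psych(psych, reliability=1.5)
        with pytest.raises(ValueError, match="variance"):
            item_responses_from_psych(psych, reliability=0.7)  # zero between-var


class TestGenerateTrial:
    @staticmethod
    def no_attrition_spec(**kw):
        defaults = dict(
            n_schools=2, classes_per_school=2, students_per_class=10,
            school_retention_posttest=1.0, student_retention_posttest=1.0,
            school_retention_followup=1.0, student_retention_followup=1.0,
            seed=0,
        )
        defaults.update(kw)
        return TrialSpec(**defaults)

    def test_cardinality_without_attrition(self, family_table):
        df = generate_trial(self.no_attrition_spec(), family_table)
        assert (df["wave"] == "pretest").sum() == 40
        assert len(df) == 120

    def test_deterministic_given_seed(self, family_table):
        d1 = generate_trial(self.no_attrition_spec(seed=5), family_table)
        d2 = generate_trial(self.no_attrition_spec(seed=5), family_table)
        pd.testing.assert_frame_equal(d1, d2)

    def test_student_retention_binomial_bound(self, family_table):
        spec = self.no_attrition_spec(
            n_schools=10, classes_per_school=4, students_per_class=25,
            student_retention_posttest=0.5, seed=9,
        )
        df = generate_trial(spec, family_table)
        n = 1000
        got = (df["wave"] == "posttest").sum()
        sigma = np.sqrt(n * 0.25)
        assert abs(got - n * 0.5) <= 3 * sigma

    def test_school_wise_attrition_drops_whole_schools(self, family_table):
        spec = self.no_attrition_spec(
            n_schools=30, classes_per_school=2, students_per_class=10,
            school_retention_posttest=0.5, seed=13,
        )
        df = generate_trial(spec, family_table)
        post_schools = set(df[df.wave == "posttest"]["school_id"])
        pre_schools = set(df[df.wave == "pretest"]["school_id"])
        assert 0 < len(post_schools) < len(pre_schools)
        # surviving schools keep all their students (student retention = 1)
        for sch in post_schools:
            pre_n = ((df.wave == "pretest") & (df.school_id == sch)).sum()
            post_n = ((df.wave == "posttest") & (df.school_id == sch)).sum()
            assert pre_n == post_n

    def test_default_retention_near_study_rates(self, family_table):
        spec = TrialSpec(n_schools=77, classes_per_school=4, students_per_class=20, seed=21)
        df = generate_trial(spec, family_table)
        n = spec.n_students
        post = (df.wave == "posttest").sum() / n
        fu = (df.wave == "followup").sum() / n
        # school-wise dropout is lumpy; generous Monte-Carlo bands
        assert post == pytest.approx(0.335, abs=0.08)
        assert fu == pytest.approx(0.243, abs=0.08)

    def test_invariants_on_generated_values(self, family_table, true_weights):
        df = generate_trial(self.no_attrition_spec(seed=2), family_table, true_weights)
        battery = ItemBattery.default()
        for col in battery.item_ids:
            assert df[col].between(0, 10).all()
        for b in true_weights:
            assert df[b].isin([0, 1]).all()
        assert df["psych_true"].between(0, 10).all()
        assert df["gender"].isin(["male", "female"]).all()

    def test_ages_nondecreasing_across_waves(self, family_table):
        df = generate_trial(self.no_attrition_spec(seed=4), family_table)
        wide = df.pivot_table(index="student_id", columns="wave", values="age_months")
        assert (wide["posttest"] > wide["pretest"]).all()
        assert (wide["followup"] > wide["posttest"]).all()

    def test_wave_ages_beyond_table_rejected(self, family_table):
        spec = self.no_attrition_spec(pretest_age_mean=239.0)
        with pytest.raises(ValueError, match="table range"):
            generate_trial(spec, family_table)

    def test_demographic_mix(self, family_table):
        spec = self.no_attrition_spec(
            n_schools=20, classes_per_school=4, students_per_class=25, seed=8
        )
        df = generate_trial(spec, family_table)
        pre = df[df.wave == "pretest"]
        assert (pre.gender == "male").mean() == pytest.approx(0.485, abs=0.04)
        assert pre.hispanic.mean() == pytest.approx(0.149, abs=0.03)
        assert (pre.race == "white").mean() == pytest.approx(0.594, abs=0.04)


class TestEndToEndRecovery:
    def test_calibration_recovers_generating_psych_slope(self, family_table, true_weights):
        # high-reliability measurement keeps errors-in-variables attenuation
        # well inside the sampling error
        spec = TrialSpec(
            n_schools=60, classes_per_school=4, students_per_class=25,
            school_retention_posttest=1.0, student_retention_posttest=1.0,
            school_retention_followup=1.0, student_retention_followup=1.0,
            reliability=0.95, psych_noise_preset="norms_like", seed=31,
        )
        df = generate_trial(spec, family_table, true_weights)
        df["psych"] = score_survey(df)
        pre = df[df.wave == "pretest"]
        rep = fit_behavior_weights(
            pre["psych"].to_numpy(), pre["age_months"].to_numpy(),
            pre["alcohol"].to_numpy(), "alcohol",
        )
        assert rep.converged
        w = true_weights["alcohol"]
        assert abs(rep.weights.b_psych - w.b_psych) <= 3 * rep.stderr[1]

    def test_matched_percentiles_track_latents(self, family_table, true_weights):
        from virtualcontrols.virtual_match import cases_from_frame, match_cohort

        spec = TrialSpec(
            n_schools=8, classes_per_school=4, students_per_class=25,
            school_retention_posttest=1.0, student_retention_posttest=1.0,
            school_retention_followup=1.0, student_retention_followup=1.0,
            psych_noise_preset="norms_like", reliability=0.95, seed=17,
        )
        df = generate_trial(spec, family_table, true_weights)
        df["psych"] = score_survey(df)
        weights = {"alcohol": true_weights["alcohol"]}
        cases = cases_from_frame(df, ("alcohol",))
        virtual, _ = match_cohort(family_table, weights, cases)
        latent = df[df.wave == "pretest"].set_index("student_id")["latent_percentile"]
        matched = pd.Series(
            {v.student_id: v.matched_percentile for v in virtual}
        )
        joined = pd.concat([latent, matched], axis=1, join="inner")
        assert np.corrcoef(joined.iloc[:, 0], joined.iloc[:, 1])[0, 1] > 0.8


class TestSurveyIO:
    def test_round_trip_with_seed_header(self, tmp_path, family_table):
        df = generate_trial(TestGenerateTrial.no_attrition_spec(), family_table)
        path = tmp_path / "survey.csv"
        write_survey(df, path, seed=0)
        assert path.read_text().startswith("# seed=0\n")
        back = read_survey(path)
        assert len(back) == len(df)
        assert back["alcohol"].equals(df["alcohol"].reset_index(drop=True))
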