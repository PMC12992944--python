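"""Scoring-engine tests: worked-example cases, cutoff boundaries, markup
semantics, prophylaxis tiers and structural properties of the score."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pydantic import ValidationError

from vtescore import (
    apply_postpartum_markup,
    compute_vte_score,
    recommend_prophylaxis,
    score_cohort,
    score_table,
)
from vtescore.types import ProphylaxisTier, RiskTier

from conftest import make_profile


class TestWorkedExampleCases:
    def test_all_cases_reproduce_their_factor_lists(self, worked_cases):
        """Each bundled VTE case scores exactly what its factor list implies."""
        df = worked_cases.df
        scored = score_table(df)
        assert (scored["pre_op_score"] == df["expected_pre_op_score"]).all()
        assert (scored["final_score"] == df["expected_final_score"]).all()

    def test_eight_cases_reach_the_pharmacologic_stratum(self, worked_cases):
        scored = score_table(worked_cases.df)
        assert int((scored["final_score"] >= 3).sum()) == 8

    def test_single_profile_path_agrees_with_table_path(self, worked_cases):
        df = worked_cases.df
        results, _ = score_cohort(
            df[[c for c in df.columns if c not in
                ("case_id", "period", "vte_event", "printed_score",
                 "expected_pre_op_score", "expected_final_score")]].to_dict("records")
        )
        assert [r.final_score for r, _plan in results] == df["expected_final_score"].tolist()


class TestCutoffBoundaries:
    @pytest.mark.parametrize(
        "field,value,expected",
        [
            ("age", 40, 1), ("age", 39, 0),
            ("bmi", 25.0, 1), ("bmi", 24.99, 0),
            ("bmi", 30.0, 2), ("bmi", 29.99, 1),
            ("parity", 3, 1), ("parity", 2, 0),
            ("gestational_age_at_delivery", 33.9, 1),
            ("gestational_age_at_delivery", 34.0, 0),
        ],
    )
    def test_inclusive_sides(self, field, value, expected):
        """Cutoffs fall on the stated inclusive side (age>=40, BMI bands,
        parity>=3, preterm strictly <34 completed weeks)."""
        r = compute_vte_score(make_profile(**{field: value}))
        assert r.final_score == expected

    @pytest.mark.parametrize("pph,extra", [(1000, 1), (999.9, 0), (0, 0)])
    def test_pph_markup_threshold_inclusive_at_1000ml(self, pph, extra):
        r = compute_vte_score(make_profile(pph_ml=pph))
        assert r.final_score == extra
        assert r.pre_op_score == 0

    def test_transfusion_triggers_markup_without_pph(self):
        r = compute_vte_score(make_profile(transfusion=True))
        assert r.final_score == 1 and r.pre_op_score == 0


class TestMarkupSemantics:
    def test_two_stage_scoring_matches_one_shot(self):
        p = make_profile(bmi=31, gestational_age_at_delivery=33, pph_ml=3000)
        pre = compute_vte_score(p, include_markup=False)
        assert pre.pre_op_score == 3 and not pre.markup_applied
        post = apply_postpartum_markup(pre, pph_ml=3000)
        assert post.final_score == 4
        assert post.final_score == compute_vte_score(p).final_score

    def test_markup_does_not_grant_intraoperative_cuff(self):
        """A patient reaching 2 only through the markup was not cuffed in
        theatre: mechanical attribution is pre-operative only."""
        pre = compute_vte_score(make_profile(bmi=27), include_markup=False)
        assert pre.pre_op_score == 1 and not pre.mechanical_during_op
        post = apply_postpartum_markup(pre, pph_ml=1200)
        assert post.final_score == 2
        assert post.risk_tier == RiskTier.moderate
        assert not post.mechanical_during_op

    def test_markup_can_raise_tier_into_pharmacologic(self):
        pre = compute_vte_score(make_profile(age=45, bmi=27), include_markup=False)
        post = apply_postpartum_markup(pre, pph_ml=1500)
        assert post.final_score == 3 and post.risk_tier == RiskTier.high

    def test_double_application_errors(self):
        r = compute_vte_score(make_profile())
        with pytest.raises(ValueError, match="already applied"):
            apply_postpartum_markup(r, pph_ml=0)

    def test_negative_volume_errors(self):
        r = compute_vte_score(make_profile(), include_markup=False)
        with pytest.raises(ValueError, match="non-negative"):
            apply_postpartum_markup(r, pph_ml=-5)

    def test_below_threshold_markup_leaves_score_unchanged(self):
        pre = compute_vte_score(make_profile(bmi=27), include_markup=False)
        post = apply_postpartum_markup(pre, pph_ml=400)
        assert post.final_score == 1


class TestAntenatalLMWHExclusion:
    def test_excluded_patients_are_not_scored(self):
        r = compute_vte_score(make_profile(on_antenatal_lmwh=True, age=45, bmi=35))
        assert r.excluded_antenatal_lmwh
        assert r.final_score == 0 and not r.components

    def test_excluded_patients_continue_lmwh(self):
        r = compute_vte_score(make_profile(on_antenatal_lmwh=True))
        plan = recommend_prophylaxis(r, weight=60)
        assert plan.tier == ProphylaxisTier.antenatal_lmwh_continued

    def test_markup_on_excluded_patient_errors(self):
        r = compute_vte_score(make_profile(on_antenatal_lmwh=True))
        with pytest.raises(ValueError, match="excluded"):
            apply_postpartum_markup(r, pph_ml=1500)


class TestProphylaxisPlan:
    @pytest.mark.parametrize(
        "score_profile,weight,tier,dose",
        [
            (dict(bmi=27, pre_eclampsia=True), 60, ProphylaxisTier.mechanical, None),
            (dict(age=45, bmi=31), 70, ProphylaxisTier.mechanical_plus_pharmacologic, 40),
            (dict(age=45, bmi=31, pre_eclampsia=True), 105,
             ProphylaxisTier.mechanical_plus_pharmacologic, 60),
            (dict(), 60, ProphylaxisTier.early_mobilization_only, None),
        ],
    )
    def test_tiers_and_weight_banded_dosing(self, score_profile, weight, tier, dose):
        r = compute_vte_score(make_profile(**score_profile))
        plan = recommend_prophylaxis(r, weight=weight)
        assert plan.tier == tier
        assert plan.dose_mg == dose
        if dose:
            assert plan.drug == "enoxaparin" and plan.duration_days == 10

    def test_weight_boundary_at_100kg(self):
        r = compute_vte_score(make_profile(age=45, bmi=31))
        assert recommend_prophylaxis(r, weight=100).dose_mg == 60
        assert recommend_prophylaxis(r, weight=99.9).dose_mg == 40

    def test_pharmacologic_tier_requires_weight(self):
        r = compute_vte_score(make_profile(age=45, bmi=31))
        with pytest.raises(ValueError, match="weight"):
            recommend_prophylaxis(r, weight=None)


class TestValidation:
    def test_missing_mandatory_field_names_it(self):
        p = make_profile()
        del p["age"]
        with pytest.raises(ValidationError, match="age"):
            compute_vte_score(p)

    @pytest.mark.parametrize("field,value", [("bmi", -1), ("pph_ml", -10), ("age", 8)])
    def test_invalid_field_values_error(self, field, value):
        with pytest.raises(ValidationError, match=field):
            compute_vte_score(make_profile(**{field: value}))


class TestScoreCohort:
    def test_empty_cohort(self):
        results, summary = score_cohort([])
        assert results == [] and summary.n == 0
        assert sum(summary.score_counts.values()) == 0

    def test_summary_counts_sum_to_cohort_size(self, worked_cases):
        df = worked_cases.df
        profiles = df[[c for c in df.columns if c not in
                       ("case_id", "period", "vte_event", "printed_score",
                        "expected_pre_op_score", "expected_final_score")]].to_dict("records")
        _, summary = score_cohort(profiles)
        assert sum(summary.score_counts.values()) + summary.excluded_antenatal_lmwh == summary.n == 16

    def test_antenatal_lmwh_counted_separately(self):
        _, summary = score_cohort([make_profile(on_antenatal_lmwh=True)])
        assert summary.excluded_antenatal_lmwh == 1
        assert sum(summary.score_counts.values()) == 0

    def test_invalid_record_names_its_index(self):
        with pytest.raises(ValueError, match="index 1"):
            score_cohort([make_profile(), make_profile(bmi=-2)])


BOOL_FACTORS = [
    "pre_eclampsia", "multiple_pregnancy", "prolonged_labor_gt24h", "stillbirth",
    "medical_comorbidity", "low_risk_thrombophilia", "current_smoker",
    "gross_varicose_veins", "current_systemic_infection", "immobility",
    "family_history_vte",
]

profiles = st.builds(
    make_profile,
    age=st.integers(12, 60),
    bmi=st.floats(16, 45),
    parity=st.integers(0, 6),
    gestational_age_at_delivery=st.floats(24, 42),
    cs_urgency=st.sampled_from(["elective", "emergency"]),
    pph_ml=st.floats(0, 4000),
    transfusion=st.booleans(),
    **{f: st.booleans() for f in BOOL_FACTORS},
)


class TestScoreProperties:
    @settings(max_examples=150, derandomize=True)
    @given(profiles)
    def test_final_score_is_sum_of_components(self, p):
        r = compute_vte_score(p)
        assert r.final_score == sum(c.points for c in r.components)
        assert r.final_score - r.pre_op_score in (0, 1)

    @settings(max_examples=150, derandomize=True)
    @given(profiles, st.sampled_from(BOOL_FACTORS))
    def test_setting_a_factor_never_decreases_the_score(self, p, factor):
        base = compute_vte_score({**p, factor: False}).final_score
        raised = compute_vte_score({**p, factor: True}).final_score
        assert raised >= base

    @settings(max_examples=150, derandomize=True)
    @given(profiles)
    def test_bmi_components_mutually_exclusive(self, p):
        r = compute_vte_score(p)
        bmi_points = [c.points for c in r.components if c.factor_name.startswith("bmi")]
        assert len(bmi_points) <= 1
        assert sum(bmi_points) in (0, 1, 2)

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(profiles, min_size=1, max_size=8))
    def test_vectorized_table_path_matches_per_profile_path(self, ps):
        scored = score_table(pd.DataFrame(ps))
        singles = [compute_vte_score(p) for p in ps]
        assert scored["final_score"].tolist() == [r.final_score for r in singles]
        assert scored["pre_op_score"].tolist() == [r.pre_op_score for r in singles]
        assert scored["mechanical_during_op"].tolist() == [
            r.mechanical_during_op for r in singles
        ]

    @pytest.mark.parametrize(
        "field,low,high",
        [("age", 39, 40), ("bmi", 24.9, 25.0), ("bmi", 29.9, 30.0), ("pph_ml", 999, 1000)],
    )
    def test_raising_a_covariate_across_its_cutoff_never_decreases(self, field, low, high):
        assert (
            compute_vte_score(make_profile(**{field: high})).final_score
            >= compute_vte_score(make_profile(**{field: low})).final_score
        )
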