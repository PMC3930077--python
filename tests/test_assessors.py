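"""Per-factor assessor rules against the worked examples and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prognograde import assessors, engine, meta
from prognograde.assessors import (
    Thresholds,
    assess_dose_response,
    assess_effect_size_upgrade,
    assess_imprecision,
    assess_inconsistency,
    assess_indirectness,
    assess_publication_bias,
    assess_study_limitations,
    classify_effect_magnitude,
    starting_level,
)
from prognograde.model import BodyOfEvidence, EffectEstimate, Override
from prognograde.simulate import ScenarioSpec, generate_body

from conftest import make_rob, make_study


def body_of(*studies, **kw) -> BodyOfEvidence:
    kw.setdefault("factor_name", "f")
    kw.setdefault("outcome_name", "o")
    return BodyOfEvidence(studies=list(studies), **kw)


class TestStartingLevel:
    def test_all_phase1_starts_moderate(self):
        body = body_of(*[make_study(f"s{i}", phase=1) for i in range(3)])
        level, rationale = starting_level(body)
        assert level == 3
        assert "phase 1" in rationale

    def test_all_phase3_starts_high(self):
        body = body_of(*[make_study(f"s{i}", phase=3) for i in range(3)])
        assert starting_level(body)[0] == 4

    def test_tie_breaks_conservatively(self):
        body = body_of(
            make_study("a", phase=1), make_study("b", phase=1),
            make_study("c", phase=2), make_study("d", phase=2),
        )
        assert starting_level(body)[0] == 3


class TestStudyLimitations:
    def test_three_moderate_studies_are_serious(self):
        # each study: 4/6 domains at moderate risk
        body = body_of(*[make_study(f"s{i}", rob=make_rob(n_moderate=4))
                         for i in range(3)])
        a = assess_study_limitations(body)
        assert a.rating == "serious" and a.level_delta == -1

    def test_all_low_is_no_concern(self):
        body = body_of(*[make_study(f"s{i}") for i in range(3)])
        a = assess_study_limitations(body)
        assert a.rating == "no_concern" and a.level_delta == 0

    def test_all_high_is_very_serious(self):
        body = body_of(*[make_study(f"s{i}", rob=make_rob(n_high=6))
                         for i in range(3)])
        a = assess_study_limitations(body)
        assert a.rating == "very_serious" and a.level_delta == -2

    def test_unclear_pools_with_moderate(self):
        body = body_of(*[make_study(f"s{i}", rob=make_rob(n_unclear=4))
                         for i in range(3)])
        assert assess_study_limitations(body).rating == "serious"

    def test_participant_weighting_can_flip_majority(self):
        big_clean = make_study("big", n=10000)
        small_bad = [make_study(f"s{i}", n=100, rob=make_rob(n_moderate=5))
                     for i in range(2)]
        body = body_of(big_clean, *small_bad)
        assert assess_study_limitations(body).rating == "serious"
        assert (
            assess_study_limitations(body, weighting="participants").rating
            == "no_concern"
        )


class TestInconsistency:
    def test_single_study_downgrades(self, menstruation_body):
        a = assess_inconsistency(menstruation_body)
        assert a.rating == "serious" and a.level_delta == -1
        assert "not well established" in a.rationale

    def test_mixed_significant_and_null_reports_are_serious(self, age_body):
        # one significant risk estimate, two no-association reports with no
        # CIs to judge overlap
        a = assess_inconsistency(age_body)
        assert a.rating == "serious"

    def test_identical_estimates_are_consistent(self):
        studies = [make_study(f"s{i}", or_=1.9, ci=(1.6, 2.2)) for i in range(5)]
        body = body_of(*studies)
        assert assess_inconsistency(body).rating == "no_concern"

    def test_opposite_directions_with_disjoint_cis_very_serious(self):
        body = body_of(
            make_study("a", or_=2.5, ci=(2.0, 3.1)),
            make_study("b", or_=0.4, ci=(0.3, 0.55)),
        )
        a = assess_inconsistency(body)
        assert a.rating == "very_serious" and a.level_delta == -2

    def test_meaningfulness_gate_vetoes_statistical_signals(self):
        spec = ScenarioSpec(k=10, true_theta=0.3, tau=1.0, seed=11,
                            clinical_meaningfulness=False)
        body = engine.attach_pooled(generate_body(spec))
        a = assess_inconsistency(body, pooled=body.pooled)
        assert a.rating == "no_concern"
        assert "not clinically meaningful" in a.rationale

    @pytest.mark.parametrize(
        "tau, bound, comparison",
        [(0.0, 0.10, "lt"), (1.0, 0.80, "gt")],
    )
    def test_serious_rate_tracks_true_heterogeneity(self, tau, bound, comparison):
        """tau=0 bodies rarely flag; tau=1 bodies almost always do."""
        reps, flagged = 200, 0
        for i in range(reps):
            spec = ScenarioSpec(k=10, true_theta=0.3, tau=tau, n_per_study=2000,
                                clinical_meaningfulness=True, seed=50_000 + i)
            body = engine.attach_pooled(generate_body(spec))
            a = assess_inconsistency(body, pooled=body.pooled)
            flagged += a.rating in ("serious", "very_serious")
        rate = flagged / reps
        assert rate < bound if comparison == "lt" else rate > bound


class TestIndirectness:
    def test_specialty_clinic_population_is_serious(self):
        studies = [make_study(f"s{i}", indirect_population=True) for i in range(3)]
        a = assess_indirectness(body_of(*studies))
        assert a.rating == "serious"
        assert "population" in a.rationale

    def test_no_flags_is_no_concern(self, sex_body):
        assert assess_indirectness(sex_body).rating == "no_concern"

    def test_two_dimensions_in_majority_is_very_serious(self):
        studies = [
            make_study(f"s{i}", indirect_population=True, indirect_outcome=True)
            for i in range(2)
        ] + [make_study("s3")]
        assert assess_indirectness(body_of(*studies)).rating == "very_serious"


class TestImprecision:
    def test_no_estimate_reported_is_unclear(self, menstruation_body):
        a = assess_imprecision(menstruation_body)
        assert a.rating == "unclear" and a.level_delta == 0
        assert "cannot be judged" in a.rationale

    def test_events_per_variable_rule_is_reported(self, menstruation_body):
        # 134 events for 14 candidate variables fails the 10-EPV rule (140)
        a = assess_imprecision(menstruation_body)
        assert "134 events / 14 variables fails" in a.rationale
        assert "rule-of-thumb conflict" in a.rationale  # 134 >= 100 endpoint cases

    def test_majority_precise_never_downgrades(self, intensity_body):
        # few small studies, but each is adequate and reports a tight CI
        a = assess_imprecision(intensity_body)
        assert a.rating == "no_concern"

    def test_small_imprecise_narrative_body_downgrades(self):
        wide = (0.3, 3.5)  # spans null and both appreciable regions
        studies = [
            make_study(f"s{i}", n=80, or_=1.0, ci=wide, n_events=20,
                       n_prognostic_variables=5)
            for i in range(2)
        ]
        a = assess_imprecision(body_of(*studies))
        assert a.rating == "serious"

    def test_meta_pooled_wide_interval_downgrades(self):
        pooled = meta.PooledResult(
            theta_hat=0.0, se_hat=0.6, ci_low=-1.2, ci_high=1.2, q=1.0, df=1,
            p_heterogeneity=0.3, i_squared=0.0, tau_squared=0.0, k=2, total_n=500,
        )
        studies = [make_study(f"s{i}", or_=1.0, ci=(0.4, 2.6)) for i in range(2)]
        body = body_of(*studies, synthesis_mode="meta_analysis", pooled=pooled)
        assert assess_imprecision(body, pooled=pooled).rating == "serious"


class TestPublicationBias:
    def test_four_studies_exempt_with_phase_note(self):
        body = body_of(*[make_study(f"s{i}", phase=1) for i in range(4)])
        a = assess_publication_bias(body)
        assert a.rating == "no_concern"
        assert "no double-downgrade with phase" in a.rationale

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_few_studies_default_downgrade(self, k):
        body = body_of(*[make_study(f"s{i}") for i in range(k)])
        a = assess_publication_bias(body)
        assert a.rating == "serious" and a.level_delta == -1


class TestEffectMagnitude:
    @pytest.mark.parametrize(
        "measure, point, expected",
        [
            ("OR", 6.2, "large"),
            ("OR", 2.08, "small"),   # below the 2.5 rule-of-thumb cut-off
            ("OR", 0.2, "large"),    # reciprocal 5.0 >= 4.25, protective
            ("OR", 2.5, "moderate"),
            ("OR", 4.25, "large"),
            ("SMD", 0.5, "moderate"),
            ("SMD", -0.85, "large"),
            ("SMD", 0.3, "small"),
        ],
    )
    def test_rules_of_thumb(self, measure, point, expected):
        e = EffectEstimate(measure=measure, point=point)
        assert classify_effect_magnitude(e) == expected

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(0.01, 100.0))
    def test_reciprocal_symmetry(self, x):
        a = classify_effect_magnitude(EffectEstimate(measure="OR", point=x))
        b = classify_effect_magnitude(EffectEstimate(measure="OR", point=1.0 / x))
        assert a == b


class TestEffectSizeUpgrade:
    def test_pooled_moderate_effect_upgrades(self):
        pooled = meta.PooledResult(
            theta_hat=math.log(3.0), se_hat=0.1, ci_low=math.log(2.5),
            ci_high=math.log(3.7), q=1.0, df=2, p_heterogeneity=0.6,
            i_squared=0.0, tau_squared=0.0, k=3, total_n=900,
        )
        studies = [make_study(f"s{i}", or_=3.0, ci=(2.4, 3.8)) for i in range(3)]
        body = body_of(*studies, synthesis_mode="meta_analysis", pooled=pooled)
        a = assess_effect_size_upgrade(body, pooled=pooled)
        assert a.rating == "present" and a.level_delta == 1

    def test_split_magnitudes_need_an_override(self):
        # one large (6.2) and one small (2.08) estimate: absent by default,
        # present only under a recorded reviewer override
        studies = [
            make_study("monastero", or_=6.2),
            make_study("ozge", or_=2.08),
        ]
        body = body_of(*studies)
        assert assess_effect_size_upgrade(body).rating == "absent"
        over = body.model_copy(update={"overrides": {
            "effect_size": Override(
                rating="present",
                justification="collectively judged large enough to upgrade",
            )
        }})
        a = assess_effect_size_upgrade(over)
        assert a.rating == "present" and a.overridden and a.level_delta == 1
        assert "collectively judged" in a.rationale

    def test_null_effects_are_absent(self):
        studies = [make_study(f"s{i}", or_=1.02, ci=(0.9, 1.15)) for i in range(4)]
        assert assess_effect_size_upgrade(body_of(*studies)).rating == "absent"


class TestDoseResponse:
    def test_no_exposure_levels_not_applicable(self, sex_body):
        a = assess_dose_response(sex_body)
        assert a.rating == "not_applicable" and a.level_delta == 0

    def test_monotone_series_is_present(self):
        s = make_study("anda", exposure_levels=[
            {"dose": d, "effect": {"measure": "OR", "point": p}}
            for d, p in [(1, 1.2), (3, 1.7), (5, 2.1)]
        ])
        a = assess_dose_response(body_of(s))
        assert a.rating == "present" and a.level_delta == 1

    def test_opposite_directions_across_studies_absent(self):
        up = make_study("up", exposure_levels=[
            {"dose": d, "effect": {"measure": "OR", "point": p}}
            for d, p in [(1, 1.2), (3, 1.7), (5, 2.1)]
        ])
        down = make_study("down", exposure_levels=[
            {"dose": d, "effect": {"measure": "OR", "point": p}}
            for d, p in [(1, 2.1), (3, 1.7), (5, 1.2)]
        ])
        assert assess_dose_response(body_of(up, down)).rating == "absent"


class TestOverridesAndDeterminism:
    @pytest.mark.parametrize("factor, rating", [
        ("study_limitations", "very_serious"),
        ("inconsistency", "no_concern"),
        ("imprecision", "serious"),
        ("dose_response", "present"),
    ])
    def test_override_always_wins(self, sex_body, factor, rating):
        body = sex_body.model_copy(update={"overrides": {
            factor: Override(rating=rating, justification="panel decision")
        }})
        fn = {
            "study_limitations": assess_study_limitations,
            "inconsistency": assess_inconsistency,
            "imprecision": assess_imprecision,
            "dose_response": assess_dose_response,
        }[factor]
        a = fn(body)
        assert a.rating == rating and a.overridden
        assert "panel decision" in a.rationale

    def test_assessors_are_order_insensitive(self, age_body, sex_body):
        for body in (age_body, sex_body):
            rev = body.model_copy(update={"studies": list(reversed(body.studies))})
            for fn in (assess_study_limitations, assess_inconsistency,
                       assess_indirectness, assess_imprecision,
                       assess_publication_bias, assess_effect_size_upgrade,
                       assess_dose_response):
                assert fn(body).rating == fn(rev).rating
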