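import itertools

import numpy as np
import pytest

from sepscore.patient_model import TriState
from sepscore.severity_scores import (
    MAX_SCORES,
    SCORERS,
    SepsisCategory,
    classify_sepsis,
    curb65_score,
    meds_objective,
    meds_score,
    mrems_o2_adjusted,
    mrems_score,
    rems_score,
)

from conftest import make_resolved, random_resolved
from table_oracle import ORACLES, band_lookup

YES = TriState.YES


def max_meds_patient(**extra):
    return make_resolved(
        age=70, terminal_illness=YES, nursing_home_resident=YES,
        lower_respiratory_infection=YES, bands_pct=8, platelets=100,
        resp_rate=24, shock_after_fluids=YES, altered_mental_status=YES,
        **extra,
    )


class TestMeds:
    def test_all_normal_scores_zero(self, normal_adult):
        assert meds_score(normal_adult).total == 0

    def test_every_criterion_met_scores_maximum(self):
        assert meds_score(max_meds_patient()).total == 27

    def test_age_and_tachypnea_only(self):
        r = make_resolved(age=70, resp_rate=24)
        assert meds_score(r).total == 6  # 3 age + 3 tachypnea

    @pytest.mark.parametrize("kwargs,expected", [
        ({"age": 65}, 0),                 # strictly > 65
        ({"age": 66}, 3),
        ({"platelets": 150}, 0),          # strictly < 150
        ({"platelets": 149}, 3),
        ({"bands_pct": 5}, 0),            # strictly > 5
        ({"bands_pct": 6}, 3),
        ({"resp_rate": 20}, 0),           # strictly > 20
        ({"resp_rate": 21}, 3),
        ({"spo2": 90}, 0),                # strictly < 90
        ({"spo2": 89}, 3),
        ({"on_supplemental_o2": YES}, 3),
    ])
    def test_threshold_boundaries(self, kwargs, expected):
        assert meds_score(make_resolved(**kwargs)).total == expected


class TestMedsObjective:
    def test_max_patient_drops_subjective_points(self):
        assert meds_objective(max_meds_patient()).total == 27 - 6 - 2 == 19

    def test_only_subjective_criteria_scores_zero(self):
        r = make_resolved(terminal_illness=YES, altered_mental_status=YES)
        assert meds_objective(r).total == 0

    def test_all_normal_zero(self, normal_adult):
        assert meds_objective(normal_adult).total == 0


def rems_patient(age, hr, rr, map_, spo2, gcs=15, ams=TriState.NO):
    return make_resolved(
        age=age, heart_rate=hr, resp_rate=rr, map=map_, spo2=spo2, gcs=gcs,
        altered_mental_status=ams,
    )


class TestRems:
    def test_age_band_only(self):
        assert rems_score(rems_patient(80, 70, 12, 80, 95)).total == 6

    def test_all_zero_bands(self):
        assert rems_score(rems_patient(40, 80, 16, 90, 98)).total == 0

    def test_mixed_bands(self):
        # age 70->5, HR 120->2, RR 30->1, MAP 60->2, SpO2 88->1, GCS 12->1
        assert rems_score(rems_patient(70, 120, 30, 60, 88, gcs=12)).total == 12

    def test_worst_bands_score_maximum(self):
        assert rems_score(rems_patient(80, 190, 60, 40, 70, gcs=3)).total == 26

    @pytest.mark.parametrize("variable,value,points", [
        # resolutions of the printed table's gaps and duplicates
        ("heart_rate", 50, 3), ("heart_rate", 60, 2), ("heart_rate", 39, 4),
        ("heart_rate", 40, 3),
        ("spo2", 70, 4), ("spo2", 74, 4), ("spo2", 75, 3),
        ("spo2", 90, 0), ("spo2", 89, 1),
        ("age", 65, 5), ("age", 64, 3),
        ("resp_rate", 5, 4), ("resp_rate", 6, 2),
        ("map", 49, 4), ("map", 50, 2),
    ])
    def test_printed_table_gap_resolutions(self, variable, value, points):
        base = dict(age=40, heart_rate=80, resp_rate=16, map=90, spo2=98,
                    gcs=15)
        base[variable] = value
        r = make_resolved(**base)
        assert rems_score(r).component(variable).points == points

    @pytest.mark.parametrize("variable,lo,hi,center", [
        ("heart_rate", 20, 250, 85),
        ("resp_rate", 1, 80, 16),
        ("map", 20, 200, 90),
        ("gcs", 3, 15, 15),
    ])
    def test_points_monotone_away_from_normal(self, variable, lo, hi, center):
        """Worsening one vital in either direction never lowers its band."""
        def pts(v):
            base = dict(age=40, heart_rate=80, resp_rate=16, map=90,
                        spo2=98, gcs=15)
            base[variable] = v
            return rems_score(make_resolved(**base)).component(variable).points

        up = [pts(v) for v in range(center, hi + 1)]
        down = [pts(v) for v in range(center, lo - 1, -1)]
        assert up == sorted(up)
        assert down == sorted(down)

    def test_spo2_monotone_decreasing(self):
        pts = [rems_score(rems_patient(40, 80, 16, 90, v)).component("spo2").points
               for v in range(100, 49, -1)]
        assert pts == sorted(pts)


class TestMrems:
    def test_mixed_bands_with_ams(self):
        r = rems_patient(70, 120, 30, 60, 88, ams=YES)
        assert mrems_score(r).total == 12

    def test_all_normal_no_ams(self, normal_adult):
        assert mrems_score(normal_adult).total == 0

    def test_ams_isolated_component_worth_one(self):
        base = rems_patient(70, 120, 30, 60, 88)
        with_ams = rems_patient(70, 120, 30, 60, 88, ams=YES)
        assert mrems_score(with_ams).total - mrems_score(base).total == 1

    def test_worst_bands_score_maximum(self):
        r = rems_patient(80, 190, 60, 40, 70, ams=YES)
        assert mrems_score(r).total == 23

    def test_gcs_never_consulted(self):
        a = rems_patient(70, 120, 30, 60, 88, gcs=3)
        b = rems_patient(70, 120, 30, 60, 88, gcs=15)
        assert mrems_score(a).total == mrems_score(b).total


class TestMremsO2Adjusted:
    def test_reassigns_low_spo2_component_to_midpoint(self):
        r = make_resolved(spo2=95, resp_rate=24, on_supplemental_o2=YES)
        base = mrems_score(r)
        adj = mrems_o2_adjusted(r)
        assert base.component("spo2").points == 0
        assert adj.component("spo2").points == 2
        assert adj.total == base.total + 2

    def test_spo2_component_three_unchanged(self):
        r = make_resolved(spo2=80, resp_rate=24)  # component 3, hypoxic
        assert mrems_o2_adjusted(r).total == mrems_score(r).total

    def test_not_hypoxic_or_tachypneic_unchanged(self):
        r = make_resolved(spo2=95, resp_rate=16)
        assert mrems_o2_adjusted(r).total == mrems_score(r).total


class TestCurb65:
    def test_all_criteria_met_scores_five(self):
        r = make_resolved(age=80, confusion=YES, bun=9, bun_unit="mmol/L",
                          resp_rate=35, sbp=85, dbp=50)
        assert curb65_score(r).total == 5

    def test_all_normal_zero(self, normal_adult):
        assert curb65_score(normal_adult).total == 0

    @pytest.mark.parametrize("kwargs,expected", [
        ({"bun": 7.0, "bun_unit": "mmol/L"}, 0),     # strictly > 7
        ({"bun": 7.1, "bun_unit": "mmol/L"}, 1),
        ({"bun": 19.6, "bun_unit": "mg/dL"}, 0),     # exactly 7 mmol/L
        ({"bun": 22.4, "bun_unit": "mg/dL"}, 1),     # 8 mmol/L
        ({"age": 65}, 1),                            # >= 65, unlike MEDS
        ({"age": 64}, 0),
        ({"resp_rate": 30}, 0),                      # strictly > 30
        ({"resp_rate": 31}, 1),
        ({"sbp": 90, "dbp": 70}, 0),
        ({"sbp": 89, "dbp": 70}, 1),
        ({"sbp": 120, "dbp": 59}, 1),
    ])
    def test_threshold_boundaries(self, kwargs, expected):
        assert curb65_score(make_resolved(**kwargs)).total == expected


class TestScoreInvariants:
    def test_totals_match_independent_table_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10_000):
            r = random_resolved(rng)
            for name, scorer in SCORERS.items():
                res = scorer(r)
                assert res.total == ORACLES[name](r), (name, r)
                assert res.total == sum(c.points for c in res.components)
                assert 0 <= res.total <= MAX_SCORES[name]

    def test_imputed_fields_contribute_zero_everywhere(self):
        r = make_resolved()  # everything imputed
        for name, scorer in SCORERS.items():
            assert scorer(r).total == 0, name

    def test_every_rems_total_achievable(self):
        reps = {
            "age": {0: 40, 2: 50, 3: 60, 5: 70, 6: 80},
            "heart_rate": {0: 80, 2: 120, 3: 150, 4: 190},
            "resp_rate": {0: 16, 1: 30, 2: 8, 3: 40, 4: 60},
            "map": {0: 90, 2: 60, 3: 140, 4: 40},
            "spo2": {0: 98, 1: 88, 3: 80, 4: 70},
            "gcs": {0: 15, 1: 12, 2: 9, 3: 6, 4: 3},
        }
        for var, mapping in reps.items():
            for pts, value in mapping.items():
                assert band_lookup(var, value) == pts
        totals = set()
        for combo in itertools.product(*(reps[v].items() for v in reps)):
            totals.add(sum(pts for pts, _ in combo))
        assert totals == set(range(0, 27))

    def test_every_meds_and_curb_total_achievable(self):
        meds_weights = [6, 3, 3, 3, 3, 3, 2, 2, 2]
        sums = {0}
        for w in meds_weights:
            sums |= {s + w for s in sums}
        # MEDS totals 1 and 26 are unattainable with criterion weights
        # {2,2,2,3,3,3,3,3,6}; every other integer in [0, 27] is achievable
        assert sums == {0} | set(range(2, 26)) | {27}
        curb_totals = {
            sum(bits) for bits in itertools.product([0, 1], repeat=5)
        }
        assert curb_totals == set(range(0, 6))


class TestClassifySepsis:
    def test_shock_takes_precedence(self):
        r = make_resolved(temp=39, heart_rate=110, shock_after_fluids=YES,
                          lactate=5, organ_dysfunction=YES)
        c = classify_sepsis(r, infection_suspected=True)
        assert c.eligible
        assert c.category is SepsisCategory.SEPTIC_SHOCK

    def test_low_map_is_shock(self):
        r = make_resolved(temp=39, heart_rate=110, map=60)
        assert classify_sepsis(r).category is SepsisCategory.SEPTIC_SHOCK

    def test_one_sirs_flag_not_eligible(self):
        r = make_resolved(temp=39)
        c = classify_sepsis(r, infection_suspected=True)
        assert not c.eligible
        assert c.n_sirs == 1
        assert c.category is SepsisCategory.NOT_QUALIFYING

    def test_no_infection_not_eligible(self):
        r = make_resolved(temp=39, heart_rate=110)
        assert not classify_sepsis(r, infection_suspected=False).eligible

    def test_lactate_boundary_inclusive(self):
        r = make_resolved(temp=39, heart_rate=110, map=70, lactate=4.0)
        c = classify_sepsis(r)
        assert c.category is SepsisCategory.SEVERE_SEPSIS_LACTATE

    def test_lactate_before_organ_dysfunction(self):
        r = make_resolved(temp=39, heart_rate=110, map=70, lactate=4.0,
                          organ_dysfunction=YES)
        assert classify_sepsis(r).category is SepsisCategory.SEVERE_SEPSIS_LACTATE

    def test_organ_dysfunction_category(self):
        r = make_resolved(temp=39, heart_rate=110, map=70, lactate=2.0,
                          organ_dysfunction=YES)
        c = classify_sepsis(r)
        assert c.category is SepsisCategory.SEVERE_SEPSIS_ORGAN_DYSFUNCTION

    def test_eligible_without_severity_not_qualifying(self):
        r = make_resolved(temp=39, heart_rate=110, map=70)
        c = classify_sepsis(r)
        assert c.eligible
        assert c.category is SepsisCategory.NOT_QUALIFYING

    @pytest.mark.parametrize("kwargs,flag_idx", [
        ({"temp": 38.5}, 0), ({"temp": 35.5}, 0),
        ({"heart_rate": 91}, 1),
        ({"resp_rate": 21}, 2),
        ({"wbc": 13}, 3), ({"wbc": 3.5}, 3), ({"bands_pct": 11}, 3),
    ])
    def test_individual_sirs_flags(self, kwargs, flag_idx):
        c = classify_sepsis(make_resolved(**kwargs))
        assert c.sirs_flags[flag_idx]
        assert c.n_sirs == 1
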