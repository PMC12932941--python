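import random
from datetime import date, datetime, timedelta

import pytest

from periopscreen.criteria import (
    CriterionId,
    Exclusion,
    evaluate_criterion,
    evaluate_exclusions,
    evaluate_inclusion,
)
from periopscreen.simulate import SimConfig, generate_cohort
from periopscreen.types import (
    AirwayHistory,
    BmiObservation,
    DiagnosisEvent,
    LabResult,
    VitalSample,
)

import naive_oracle
from conftest import SCHED, make_case, make_patient


def _dx(code, days_back=100):
    return DiagnosisEvent(icd10=code, onset_date=SCHED.date() - timedelta(days=days_back))


def _spo2(value, minutes_back):
    return VitalSample(value=value, observed_at=SCHED - timedelta(minutes=minutes_back))


class TestIndividualCriteria:
    def test_copd_diagnosis_meets_obstructive(self):
        patient = make_patient(diagnoses=[_dx("J44.9")])
        res = evaluate_criterion(
            CriterionId.obstructive_restrictive_lung_disease, patient, make_case()
        )
        assert res.met and res.evidence

    def test_preop_flag_alone_suffices(self):
        patient = make_patient(preop_eval_flags={"supplemental_o2"})
        res = evaluate_criterion(
            CriterionId.obstructive_restrictive_lung_disease, patient, make_case()
        )
        assert res.met

    @pytest.mark.parametrize(
        "days_back, met", [(0, True), (15, True), (30, True), (31, False), (200, False)]
    )
    def test_infection_window_30_days(self, days_back, met):
        patient = make_patient(diagnoses=[_dx("J18.9", days_back=days_back)])
        res = evaluate_criterion(CriterionId.acute_respiratory_infection, patient, make_case())
        assert res.met == met

    def test_spo2_mean_exactly_95_not_met(self):
        patient = make_patient(vitals=[_spo2(94, 60), _spo2(96, 120)])
        res = evaluate_criterion(CriterionId.low_preop_spo2, patient, make_case())
        assert not res.met

    def test_spo2_mean_below_95_met_and_window_respected(self):
        inside = [_spo2(93, 60), _spo2(94, 500)]
        patient = make_patient(vitals=inside)
        assert evaluate_criterion(CriterionId.low_preop_spo2, patient, make_case()).met
        # the same low values outside the 12-hour window do not count
        outside = [
            VitalSample(value=v.value, observed_at=SCHED - timedelta(hours=13))
            for v in inside
        ]
        patient = make_patient(vitals=outside)
        assert not evaluate_criterion(CriterionId.low_preop_spo2, patient, make_case()).met

    def test_spo2_no_samples_is_not_met(self):
        assert not evaluate_criterion(
            CriterionId.low_preop_spo2, make_patient(), make_case()
        ).met

    @pytest.mark.parametrize("hours, met", [(24.0, False), (24.5, True), (0, False)])
    def test_ventilator_hours_strict(self, hours, met):
        patient = make_patient(
            airway_history=AirwayHistory(max_ventilator_hours_pre_admission=hours)
        )
        res = evaluate_criterion(CriterionId.airway_pathology_history, patient, make_case())
        assert res.met == met

    @pytest.mark.parametrize(
        "value, met40, met35",
        [(40.0, False, True), (40.1, True, True), (35.0, False, False), (36.0, False, True)],
    )
    def test_bmi_thresholds_strict(self, value, met40, met35):
        patient = make_patient(
            bmi_observations=[BmiObservation(observed_at=SCHED - timedelta(days=2), value=value)]
        )
        case = make_case()
        assert evaluate_criterion(CriterionId.bmi_over_40, patient, case).met == met40
        assert evaluate_criterion(CriterionId.bmi_over_35, patient, case).met == met35

    def test_bmi_latest_observation_wins(self):
        patient = make_patient(
            bmi_observations=[
                BmiObservation(observed_at=SCHED - timedelta(days=300), value=44.0),
                BmiObservation(observed_at=SCHED - timedelta(days=3), value=29.0),
            ]
        )
        assert not evaluate_criterion(CriterionId.bmi_over_40, patient, make_case()).met

    @pytest.mark.parametrize("attempts, met", [(0, False), (1, False), (2, True)])
    def test_multiple_intubation_attempts(self, attempts, met):
        patient = make_patient(
            airway_history=AirwayHistory(prior_case_max_intubation_attempts=attempts)
        )
        res = evaluate_criterion(CriterionId.multiple_intubation_attempts, patient, make_case())
        assert res.met == met

    @pytest.mark.parametrize("duration, met", [(120, False), (121, True)])
    def test_long_surgery_boundary(self, duration, met):
        case = make_case(scheduled_duration_min=duration)
        assert evaluate_criterion(CriterionId.long_surgery, make_patient(), case).met == met

    @pytest.mark.parametrize(
        "service, name, cpts, met",
        [
            ("Thoracic Surgery", "VATS right upper lobe", [], True),
            ("Head and Neck", "Tympanomastoidectomy", [], False),
            ("Head and Neck", "Mastoidectomy", [], True),  # only one forbidden token
            ("Neurosurgery", "Craniotomy", [], False),
            ("General Surgery", "Liver Transplant", [], False),
            ("General Surgery", "Laparoscopic Cholecystectomy", [], True),
            ("General Surgery", "Hernia repair", [], False),
            ("Bariatrics", "Sleeve procedure", ["43775"], True),
            ("Bariatrics", "Sleeve procedure", ["99999"], False),
        ],
    )
    def test_surgical_site_rule(self, service, name, cpts, met):
        case = make_case(service=service, procedure_name=name, cpt_codes=cpts)
        res = evaluate_criterion(CriterionId.high_risk_surgical_site, make_patient(), case)
        assert res.met == met

    @pytest.mark.parametrize(
        "value, days_back, met",
        [(9.9, 30, True), (10.0, 30, False), (9.0, 184, False), (9.0, 182, True)],
    )
    def test_hemoglobin_threshold_and_window(self, value, days_back, met):
        patient = make_patient(
            labs=[LabResult(analyte="hemoglobin_serum", value=value,
                            collected_at=SCHED - timedelta(days=days_back))]
        )
        res = evaluate_criterion(CriterionId.low_hemoglobin, patient, make_case())
        assert res.met == met

    def test_unknown_criterion_rejected(self):
        with pytest.raises(ValueError, match="unknown criterion"):
            evaluate_criterion("not_a_criterion", make_patient(), make_case())

    def test_malformed_icd_skipped_not_met(self):
        patient = make_patient(diagnoses=[DiagnosisEvent(icd10="??", onset_date=date(2020, 1, 1))])
        res = evaluate_criterion(
            CriterionId.obstructive_restrictive_lung_disease, patient, make_case()
        )
        assert not res.met


class TestInclusionLogic:
    def test_one_major_includes(self):
        patient = make_patient(preop_eval_flags={"sleep_apnea"})
        decision = evaluate_inclusion(patient, make_case())
        assert (decision.majors_met, decision.minors_met) == (1, 0)
        assert decision.included

    def test_one_minor_does_not_include(self):
        decision = evaluate_inclusion(make_patient(), make_case(scheduled_duration_min=200))
        assert (decision.majors_met, decision.minors_met) == (0, 1)
        assert not decision.included

    def test_two_minors_include(self):
        patient = make_patient(
            labs=[LabResult(analyte="hemoglobin_serum", value=8.2,
                            collected_at=SCHED - timedelta(days=10))]
        )
        decision = evaluate_inclusion(patient, make_case(scheduled_duration_min=200))
        assert (decision.majors_met, decision.minors_met) == (0, 2)
        assert decision.included

    def test_adding_a_major_fact_never_removes_inclusion(self):
        patient = make_patient(
            labs=[LabResult(analyte="hemoglobin_serum", value=8.2,
                            collected_at=SCHED - timedelta(days=10))]
        )
        case = make_case(scheduled_duration_min=200)
        assert evaluate_inclusion(patient, case).included
        richer = patient.model_copy(deep=True)
        richer.diagnoses.append(_dx("G47.33"))
        decision = evaluate_inclusion(richer, case)
        assert decision.included and decision.majors_met == 1

    def test_no_facts_means_nothing_met(self):
        decision = evaluate_inclusion(make_patient(), make_case())
        assert (decision.majors_met, decision.minors_met) == (0, 0)
        assert not decision.included

    def test_permutation_invariance(self, small_cohort):
        rng = random.Random(5)
        cases = {c.case_id: c for c in small_cohort.cases}
        sample = small_cohort.ledger.sample(30, random_state=1)
        for case_id, pid in zip(sample["case_id"], sample["patient_id"]):
            patient = small_cohort.patients[pid]
            shuffled = patient.model_copy(deep=True)
            for lst in (shuffled.diagnoses, shuffled.labs, shuffled.vitals,
                        shuffled.bmi_observations):
                rng.shuffle(lst)
            a = evaluate_inclusion(patient, cases[case_id])
            b = evaluate_inclusion(shuffled, cases[case_id])
            assert (a.majors_met, a.minors_met, a.included, a.exclusions) == (
                b.majors_met, b.minors_met, b.included, b.exclusions
            )


class TestExclusions:
    def test_age_boundary(self):
        under = make_patient(birth_date=SCHED.date() - timedelta(days=18 * 365))  # 17y364d
        exactly_18 = make_patient(birth_date=SCHED.date().replace(year=SCHED.year - 18))
        case = make_case()
        assert Exclusion.age_lt_18 in evaluate_exclusions(under, case)
        assert Exclusion.age_lt_18 not in evaluate_exclusions(exactly_18, case)

    @pytest.mark.parametrize("gfr, excluded", [(30.0, False), (29.9, True), (None, False)])
    def test_gfr_boundary_and_absence(self, gfr, excluded):
        patient = make_patient(gfr_latest=gfr)
        flags = evaluate_exclusions(patient, make_case())
        assert (Exclusion.gfr_lt_30 in flags) == excluded

    def test_allergy_match_is_name_normalized(self):
        patient = make_patient(allergies=[" SUGAMMADEX "])
        assert Exclusion.sugammadex_allergy in evaluate_exclusions(patient, make_case())

    def test_unplanned_icu_transfer_is_not_an_exclusion(self):
        case = make_case(disposition="icu_unplanned_transfer")
        assert Exclusion.direct_icu_admission not in evaluate_exclusions(make_patient(), case)

    def test_planned_direct_icu_is_an_exclusion(self):
        case = make_case(disposition="icu_direct")
        assert Exclusion.direct_icu_admission in evaluate_exclusions(make_patient(), case)

    @pytest.mark.parametrize(
        "field, value, flag",
        [
            ("emergency", True, Exclusion.emergency),
            ("airway_plan", "non_intubated", Exclusion.non_intubated),
            ("planned_postop_intubation", True, Exclusion.planned_postop_intubation),
        ],
    )
    def test_case_level_exclusions(self, field, value, flag):
        case = make_case(**{field: value})
        assert flag in evaluate_exclusions(make_patient(), case)


def test_engine_agrees_with_naive_oracle_on_random_cohort():
    """The engine's verdicts match an independent longhand re-evaluation of
    every rule on a seeded synthetic cohort (with boundary-adjacent
    negatives included)."""
    cohort = generate_cohort(SimConfig(n_patients=800, seed=23, boundary_negative_rate=0.3))
    cases = {c.case_id: c for c in cohort.cases}
    for case_id, pid in zip(cohort.ledger["case_id"], cohort.ledger["patient_id"]):
        patient, case = cohort.patients[pid], cases[case_id]
        decision = evaluate_inclusion(patient, case)
        majors, minors, included = naive_oracle.naive_inclusion(patient, case)
        assert (decision.majors_met, decision.minors_met, decision.included) == (
            majors, minors, included
        ), case_id
        assert {e.value for e in decision.exclusions} == naive_oracle.naive_exclusions(
            patient, case
        ), case_id
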