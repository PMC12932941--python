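from datetime import datetime, time, timedelta

import pytest

from periopscreen.bpa import (
    AlertContext,
    AlertLedger,
    AvailabilityConfig,
    BpaAlert,
    EnrollmentStatus,
    classify_enrollment,
    classify_team,
    should_fire,
)
from periopscreen.criteria import Exclusion, evaluate_inclusion, screen_cases
from periopscreen.pipeline import PipelineConfig, run_pipeline
from periopscreen.types import MedAdministration, TeamCategory, TeamRoster

from conftest import SCHED, make_case, make_patient

CONFIG = AvailabilityConfig(eligible_sites=frozenset({"main_campus", "west_campus"}))
PREOP_POLL = SCHED - timedelta(days=1)  # 09:30, within pharmacy hours


def eligible_pair(**case_overrides):
    patient = make_patient(preop_eval_flags={"sleep_apnea"})
    case = make_case(**case_overrides)
    return patient, case, evaluate_inclusion(patient, case)


class TestShouldFire:
    def test_fires_preop_and_intraop(self):
        _, case, decision = eligible_pair()
        alert, reason = should_fire(case, decision, CONFIG, PREOP_POLL)
        assert reason is None and alert.context == AlertContext.preop
        alert, _ = should_fire(case, decision, CONFIG, SCHED + timedelta(minutes=10))
        assert alert.context == AlertContext.intraop

    @pytest.mark.parametrize(
        "kwargs, now, reason",
        [
            (dict(site="community"), PREOP_POLL, "site"),
            (dict(), PREOP_POLL.replace(hour=23), "hours"),
            (dict(), PREOP_POLL.replace(hour=6, minute=59), "hours"),
            (dict(), SCHED - timedelta(days=8), "window"),
            (dict(), SCHED + timedelta(minutes=90), "window"),  # past 90-min case end
            (dict(emergency=True), PREOP_POLL, "excluded"),
        ],
    )
    def test_non_firing_reasons(self, kwargs, now, reason):
        _, case, decision = eligible_pair(**kwargs)
        alert, got = should_fire(case, decision, CONFIG, now)
        assert alert is None and got == reason

    def test_ineligible_reason(self):
        patient, case = make_patient(), make_case()
        decision = evaluate_inclusion(patient, case)
        alert, reason = should_fire(case, decision, CONFIG, PREOP_POLL)
        assert alert is None and reason == "ineligible"

    def test_idempotent_per_context(self):
        _, case, decision = eligible_pair()
        ledger = AlertLedger()
        first, _ = should_fire(case, decision, CONFIG, PREOP_POLL, ledger=ledger)
        second, reason = should_fire(
            case, decision, CONFIG, PREOP_POLL + timedelta(hours=2), ledger=ledger
        )
        assert first is not None and second is None and reason == "duplicate"
        assert len(ledger) == 1
        # a later intraop poll is a distinct context
        intra, _ = should_fire(case, decision, CONFIG, SCHED + timedelta(minutes=5), ledger=ledger)
        assert intra is not None and len(ledger) == 2

    def test_replay_determinism(self):
        _, case, decision = eligible_pair()
        polls = [PREOP_POLL, PREOP_POLL + timedelta(hours=1), SCHED + timedelta(minutes=5)]

        def replay():
            ledger = AlertLedger()
            for now in polls:
                should_fire(case, decision, CONFIG, now, ledger=ledger)
            return [(a.case_id, a.context, a.fired_at) for a in ledger.alerts()]

        assert replay() == replay()

    def test_mismatched_decision_rejected(self):
        _, case, decision = eligible_pair()
        other = make_case(case_id="C999")
        with pytest.raises(ValueError, match="does not belong"):
            should_fire(other, decision, CONFIG, PREOP_POLL)


def _alert(case, decision):
    return [BpaAlert(case_id=case.case_id, fired_at=PREOP_POLL,
                     context=AlertContext.preop, decision_snapshot=decision)]


def _med(drug, source="n/a", via_bpa=False):
    return MedAdministration(drug=drug, source=source, ordered_via_bpa=via_bpa,
                             administered_at=SCHED + timedelta(minutes=60))


class TestClassifyEnrollment:
    def test_study_pathway_is_enrolled(self):
        _, case, decision = eligible_pair()
        case.meds = [_med("rocuronium"), _med("sugammadex", "study_pathway", True)]
        out = classify_enrollment(case, _alert(case, decision))
        assert out.status == EnrollmentStatus.enrolled and out.rocuronium_given

    def test_stock_bypass_is_nonadherent(self):
        _, case, decision = eligible_pair()
        case.meds = [_med("sugammadex", "standard_stock")]
        out = classify_enrollment(case, _alert(case, decision))
        assert out.status == EnrollmentStatus.nonadherent_stock_sugammadex

    def test_no_reversal_is_nonadherent_no_study_drug(self):
        _, case, decision = eligible_pair()
        case.meds = [_med("neostigmine", "standard_stock")]
        out = classify_enrollment(case, _alert(case, decision))
        assert out.status == EnrollmentStatus.nonadherent_no_study_drug

    def test_icu_transfer_outranks_meds(self):
        _, case, decision = eligible_pair(disposition="icu_unplanned_transfer")
        case.meds = [_med("sugammadex", "study_pathway", True)]
        out = classify_enrollment(case, _alert(case, decision))
        assert out.status == EnrollmentStatus.icu_disposition

    def test_exclusion_outranks_icu(self):
        _, case, decision = eligible_pair(disposition="icu_unplanned_transfer")
        out = classify_enrollment(
            case, _alert(case, decision),
            current_exclusions=frozenset({Exclusion.pregnant_lactating}),
        )
        assert out.status == EnrollmentStatus.misallocated_exclusion

    def test_unalerted_case_out_of_domain(self):
        _, case, _ = eligible_pair()
        with pytest.raises(ValueError):
            classify_enrollment(case, [])

    def test_statuses_partition_alerted_cases(self, small_cohort):
        """Every alerted case in a simulated cohort maps to exactly one
        status, and the containment chain enrolled <= alerted <= eligible
        holds."""
        from periopscreen.bpa import run_alert_polls, outcomes_frame

        decisions = {
            d.case_id: d for d in screen_cases(small_cohort.patients, small_cohort.cases)
        }
        ledger, _ = run_alert_polls(small_cohort.cases, decisions, CONFIG)
        cases_by_id = {c.case_id: c for c in small_cohort.cases}
        outcomes = []
        for case_id in sorted(ledger.case_ids()):
            case = cases_by_id[case_id]
            outcomes.append(classify_enrollment(case, ledger.for_case(case_id)))
        assert len({o.case_id for o in outcomes}) == len(outcomes)
        statuses = {o.status for o in outcomes}
        assert statuses <= set(EnrollmentStatus)
        eligible_ids = {cid for cid, d in decisions.items() if d.included}
        enrolled_ids = {o.case_id for o in outcomes if o.status == EnrollmentStatus.enrolled}
        assert enrolled_ids <= ledger.case_ids() <= eligible_ids


@pytest.mark.parametrize(
    "crna, resident, expected",
    [
        (True, True, TeamCategory.full_team),
        (True, False, TeamCategory.attending_crna),
        (False, True, TeamCategory.attending_resident),
        (False, False, TeamCategory.solo_attending),
    ],
)
def test_classify_team_partitions_all_rosters(crna, resident, expected):
    roster = TeamRoster(attending_id="A1", crna_present=crna, resident_present=resident)
    assert classify_team(roster) == expected


def test_availability_config_validation():
    with pytest.raises(ValueError):
        AvailabilityConfig(eligible_sites=frozenset())
    with pytest.raises(ValueError):
        AvailabilityConfig(
            eligible_sites=frozenset({"x"}), pharmacy_open=time(22), pharmacy_close=time(7)
        )
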