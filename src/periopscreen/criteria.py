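"""Rule engine for the respiratory-risk eligibility phenotype.

Eleven inclusion criteria (6 major, 5 minor) plus a set of hard exclusions
are evaluated for a (patient, case) pair at an ``as_of`` instant. Only facts
timestamped at or before ``as_of`` and inside each criterion's lookback
window are considered; untimestamped facts (preoperative-evaluation flags,
airway history, demographic fields) are always visible. A case is included
when at least one major criterion or at least two minor criteria are met.

All numeric thresholds are strict inequalities: mean SpO2 < 95, BMI > 40 /
> 35, hemoglobin < 10 g/dL, scheduled duration > 120 min, ventilation
> 24 h, > 1 intubation attempt, GFR < 30, age < 18 full years.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, datetime, timedelta
from enum import Enum

import pandas as pd

from .codes import normalize_icd
from .config import CriteriaConfig, default_criteria_config
from .errors import InvalidCodeError
from .types import Analyte, AirwayPlan, Disposition, PatientRecord, PreopFlag, SurgicalCase, VitalKind

logger = logging.getLogger(__name__)

__all__ = [
    "CriterionId",
    "Tier",
    "Exclusion",
    "CriterionResult",
    "EligibilityDecision",
    "MAJOR_CRITERIA",
    "MINOR_CRITERIA",
    "evaluate_criterion",
    "evaluate_exclusions",
    "evaluate_inclusion",
    "screen_cases",
    "decisions_frame",
]


class Tier(str, Enum):
    major = "major"
    minor = "minor"


class CriterionId(str, Enum):
    # major
    obstructive_restrictive_lung_disease = "obstructive_restrictive_lung_disease"
    acute_respiratory_infection = "acute_respiratory_infection"
    obstructive_sleep_apnea = "obstructive_sleep_apnea"
    low_preop_spo2 = "low_preop_spo2"
    airway_pathology_history = "airway_pathology_history"
    bmi_over_40 = "bmi_over_40"
    # minor
    multiple_intubation_attempts = "multiple_intubation_attempts"
    long_surgery = "long_surgery"
    high_risk_surgical_site = "high_risk_surgical_site"
    bmi_over_35 = "bmi_over_35"
    low_hemoglobin = "low_hemoglobin"


MAJOR_CRITERIA: tuple[CriterionId, ...] = (
    CriterionId.obstructive_restrictive_lung_disease,
    CriterionId.acute_respiratory_infection,
    CriterionId.obstructive_sleep_apnea,
    CriterionId.low_preop_spo2,
    CriterionId.airway_pathology_history,
    CriterionId.bmi_over_40,
)
MINOR_CRITERIA: tuple[CriterionId, ...] = (
    CriterionId.multiple_intubation_attempts,
    CriterionId.long_surgery,
    CriterionId.high_risk_surgical_site,
    CriterionId.bmi_over_35,
    CriterionId.low_hemoglobin,
)
_TIER = {c: Tier.major for c in MAJOR_CRITERIA} | {c: Tier.minor for c in MINOR_CRITERIA}


class Exclusion(str, Enum):
    age_lt_18 = "age_lt_18"
    pregnant_lactating = "pregnant_lactating"
    neuromuscular_disease = "neuromuscular_disease"
    gfr_lt_30 = "gfr_lt_30"
    sugammadex_allergy = "sugammadex_allergy"
    planned_postop_intubation = "planned_postop_intubation"
    direct_icu_admission = "direct_icu_admission"
    non_intubated = "non_intubated"
    emergency = "emergency"


@dataclass(frozen=True)
class CriterionResult:
    criterion_id: CriterionId
    tier: Tier
    met: bool
    evidence: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.met and not self.evidence:
            raise ValueError(f"{self.criterion_id.value}: met without evidence")


@dataclass(frozen=True)
class EligibilityDecision:
    case_id: str
    majors_met: int
    minors_met: int
    included: bool
    exclusions: frozenset[Exclusion]
    criterion_results: tuple[CriterionResult, ...]
    evaluated_at: datetime

    def __post_init__(self) -> None:
        majors = sum(1 for r in self.criterion_results if r.met and r.tier == Tier.major)
        minors = sum(1 for r in self.criterion_results if r.met and r.tier == Tier.minor)
        if (majors, minors) != (self.majors_met, self.minors_met):
            raise ValueError("criterion counts inconsistent with results")
        if self.included != (self.majors_met >= 1 or self.minors_met >= 2):
            raise ValueError("inclusion verdict inconsistent with criterion counts")

    @property
    def excluded(self) -> bool:
        return bool(self.exclusions)


def _visible_diagnoses(patient: PatientRecord, as_of: datetime):
    return [d for d in patient.diagnoses if d.onset_date <= as_of.date()]


def _match_any(patient: PatientRecord, set_name: str, as_of: datetime, cfg: CriteriaConfig,
               earliest: date | None = None) -> list[str]:
    code_set = cfg.code_sets[set_name]
    hits = []
    for dx in _visible_diagnoses(patient, as_of):
        if earliest is not None and dx.onset_date < earliest:
            continue
        try:
            if code_set.matches(dx.icd10):
                hits.append(f"diagnosis {normalize_icd(dx.icd10)} onset {dx.onset_date}")
        except InvalidCodeError:
            # malformed facts are skipped, never silently treated as met
            logger.warning(
                "patient %s: skipping malformed ICD code %r", patient.patient_id, dx.icd10
            )
    return hits


def evaluate_criterion(
    criterion_id: CriterionId | str,
    patient: PatientRecord,
    case: SurgicalCase,
    as_of: datetime | None = None,
    cfg: CriteriaConfig | None = None,
) -> CriterionResult:
    """Evaluate one inclusion criterion; deterministic in its arguments.

    ``as_of`` defaults to the case's scheduled start. Raises ``ValueError``
    for an unknown criterion id.
    """
    try:
        cid = CriterionId(criterion_id)
    except ValueError:
        raise ValueError(f"unknown criterion id: {criterion_id!r}") from None
    cfg = cfg or default_criteria_config()
    as_of = as_of or case.scheduled_start
    start = case.scheduled_start
    evidence: list[str] = []

    if cid == CriterionId.obstructive_restrictive_lung_disease:
        evidence += _match_any(patient, cid.value, as_of, cfg)
        for flag in (PreopFlag.copd, PreopFlag.supplemental_o2, PreopFlag.lung_transplant):
            if flag in patient.preop_eval_flags:
                evidence.append(f"preop flag {flag.value}")

    elif cid == CriterionId.acute_respiratory_infection:
        earliest = start.date() - timedelta(days=cfg.acute_infection_days)
        evidence += _match_any(patient, cid.value, as_of, cfg, earliest=earliest)
        if PreopFlag.recent_uri in patient.preop_eval_flags:
            evidence.append("preop flag recent_uri")

    elif cid == CriterionId.obstructive_sleep_apnea:
        evidence += _match_any(patient, cid.value, as_of, cfg)
        if PreopFlag.sleep_apnea in patient.preop_eval_flags:
            evidence.append("preop flag sleep_apnea")

    elif cid == CriterionId.low_preop_spo2:
        lo = start - timedelta(hours=cfg.spo2_hours)
        samples = [
            v.value
            for v in patient.vitals
            if v.kind == VitalKind.spo2 and lo < v.observed_at <= min(start, as_of)
        ]
        if samples:
            mean = sum(samples) / len(samples)
            if mean < cfg.spo2_mean_pct:
                evidence.append(f"mean SpO2 {mean:.2f}% over {len(samples)} samples in 12 h window")
        # no samples in the window: criterion is not met (absence is not risk)

    elif cid == CriterionId.airway_pathology_history:
        hx = patient.airway_history
        if hx.max_ventilator_hours_pre_admission > cfg.ventilator_hours:
            evidence.append(f"ventilator {hx.max_ventilator_hours_pre_admission:g} h pre-admission")
        if hx.tracheostomy_pre_admission:
            evidence.append("tracheostomy prior to admission")

    elif cid in (CriterionId.bmi_over_40, CriterionId.bmi_over_35):
        threshold = cfg.bmi_major if cid == CriterionId.bmi_over_40 else cfg.bmi_minor
        obs = [b for b in patient.bmi_observations if b.observed_at <= min(start, as_of)]
        if obs:
            latest = obs[-1]  # bmi_observations sorted on construction
            if latest.value > threshold:
                evidence.append(f"BMI {latest.value:g} at {latest.observed_at}")

    elif cid == CriterionId.multiple_intubation_attempts:
        attempts = patient.airway_history.prior_case_max_intubation_attempts
        if attempts > cfg.intubation_attempts:
            evidence.append(f"{attempts} intubation attempts documented in a prior case")

    elif cid == CriterionId.long_surgery:
        if case.scheduled_duration_min > cfg.long_surgery_min:
            evidence.append(f"scheduled duration {case.scheduled_duration_min} min")

    elif cid == CriterionId.high_risk_surgical_site:
        evidence += _surgical_site_evidence(case, cfg)

    elif cid == CriterionId.low_hemoglobin:
        lo = start - timedelta(days=cfg.hemoglobin_days)
        for lab in patient.labs:
            if (
                lab.analyte == Analyte.hemoglobin_serum
                and lo < lab.collected_at <= min(start, as_of)
                and lab.value < cfg.hemoglobin_g_dl
            ):
                evidence.append(f"hemoglobin {lab.value:g} g/dL at {lab.collected_at}")

    return CriterionResult(
        criterion_id=cid, tier=_TIER[cid], met=bool(evidence), evidence=tuple(evidence)
    )


def _surgical_site_evidence(case: SurgicalCase, cfg: CriteriaConfig) -> list[str]:
    """Upper abdominal / intrathoracic / head-and-neck surgery text rule."""
    rule = cfg.surgical_site
    name = case.procedure_name.lower()
    # hard requirements
    if case.service == rule.excluded_service:
        return []
    if rule.transplant_token.lower() in name:
        return []
    evidence: list[str] = []
    tokens = rule.service_tokens.get(case.service, ())
    for tok in tokens:
        if tok.lower() in name:
            evidence.append(f"service {case.service!r}, procedure token {tok!r}")
    if case.service == rule.head_neck_service:
        found = [t for t in rule.head_neck_forbidden_tokens if t.lower() in name]
        disqualified = (
            len(found) == len(rule.head_neck_forbidden_tokens)
            if rule.head_neck_rule == "both"
            else len(found) > 0
        )
        if not disqualified:
            evidence.append(f"service {rule.head_neck_service!r} without forbidden pattern")
    for cpt in case.cpt_codes:
        if cpt in rule.cpt_codes:
            evidence.append(f"CPT {cpt}")
    return evidence


def _age_years(birth_date: date, at: date) -> int:
    """Completed years between birth_date and `at` (anniversary arithmetic)."""
    years = at.year - birth_date.year
    anniversary_not_reached = (at.month, at.day) < (birth_date.month, birth_date.day)
    return years - int(anniversary_not_reached)


def evaluate_exclusions(
    patient: PatientRecord,
    case: SurgicalCase,
    as_of: datetime | None = None,
    cfg: CriteriaConfig | None = None,
) -> frozenset[Exclusion]:
    """Hard exclusions for a (patient, case) pair.

    Direct ICU admission is flagged only when known preoperatively (a planned
    ICU disposition); unplanned postoperative ICU transfers are not an
    exclusion at evaluation time. Absent GFR does not exclude.
    """
    cfg = cfg or default_criteria_config()
    as_of = as_of or case.scheduled_start
    flags: set[Exclusion] = set()
    if _age_years(patient.birth_date, case.scheduled_start.date()) < cfg.adult_age_years:
        flags.add(Exclusion.age_lt_18)
    if patient.pregnant_or_lactating:
        flags.add(Exclusion.pregnant_lactating)
    if patient.neuromuscular_disease:
        flags.add(Exclusion.neuromuscular_disease)
    if patient.gfr_latest is None:
        logger.debug("patient %s: no GFR on record, not excluded on GFR", patient.patient_id)
    elif patient.gfr_latest < cfg.gfr_exclusion:
        flags.add(Exclusion.gfr_lt_30)
    if any(a.strip().lower() == "sugammadex" for a in patient.allergies):
        flags.add(Exclusion.sugammadex_allergy)
    if case.planned_postop_intubation:
        flags.add(Exclusion.planned_postop_intubation)
    if case.disposition == Disposition.icu_direct:
        flags.add(Exclusion.direct_icu_admission)
    if case.airway_plan == AirwayPlan.non_intubated:
        flags.add(Exclusion.non_intubated)
    if case.emergency:
        flags.add(Exclusion.emergency)
    return frozenset(flags)


def evaluate_inclusion(
    patient: PatientRecord,
    case: SurgicalCase,
    as_of: datetime | None = None,
    cfg: CriteriaConfig | None = None,
) -> EligibilityDecision:
    """Aggregate all eleven criteria plus exclusions into a decision.

    The verdict is invariant to the storage order of patient facts.
    """
    cfg = cfg or default_criteria_config()
    as_of = as_of or case.scheduled_start
    results = tuple(
        evaluate_criterion(cid, patient, case, as_of=as_of, cfg=cfg)
        for cid in (*MAJOR_CRITERIA, *MINOR_CRITERIA)
    )
    majors = sum(1 for r in results if r.met and r.tier == Tier.major)
    minors = sum(1 for r in results if r.met and r.tier == Tier.minor)
    return EligibilityDecision(
        case_id=case.case_id,
        majors_met=majors,
        minors_met=minors,
        included=majors >= 1 or minors >= 2,
        exclusions=evaluate_exclusions(patient, case, as_of=as_of, cfg=cfg),
        criterion_results=results,
        evaluated_at=as_of,
    )


def screen_cases(
    patients: dict[str, PatientRecord],
    cases: list[SurgicalCase],
    as_of: datetime | None = None,
    cfg: CriteriaConfig | None = None,
) -> list[EligibilityDecision]:
    """Evaluate every case against its patient record."""
    cfg = cfg or default_criteria_config()
    return [
        evaluate_inclusion(patients[c.patient_id], c, as_of=as_of, cfg=cfg) for c in cases
    ]


def decisions_frame(decisions: list[EligibilityDecision]) -> pd.DataFrame:
    """Tabulate decisions: one row per case with per-criterion booleans."""
    rows = []
    for d in decisions:
        row: dict[str, object] = {
            "case_id": d.case_id,
            "included": d.included,
            "majors_met": d.majors_met,
            "minors_met": d.minors_met,
            "excluded": d.excluded,
            "exclusions": ";".join(sorted(e.value for e in d.exclusions)),
            "evaluated_at": d.evaluated_at.isoformat(),
        }
        for r in d.criterion_results:
            row[r.criterion_id.value] = r.met
        rows.append(row)
    return pd.DataFrame(rows)
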