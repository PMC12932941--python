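"""Domain types for patient-level EHR facts and surgical-case records.

All timestamps are timezone-naive local clinical time at second resolution;
dates are calendar dates. Types are pydantic models so the interchange
readers get field validation and coercion for free; list-valued facts are
sorted by their timestamps on construction so downstream logic is invariant
to storage order.
"""

from __future__ import annotations

from datetime import date, datetime
from enum import Enum
from math import isfinite
from typing import Optional

from pydantic import BaseModel, Field, field_serializer, field_validator, model_validator

__all__ = [
    "Sex",
    "PreopFlag",
    "Analyte",
    "VitalKind",
    "AirwayPlan",
    "DelayReason",
    "Disposition",
    "Drug",
    "MedSource",
    "TeamCategory",
    "DiagnosisEvent",
    "LabResult",
    "VitalSample",
    "BmiObservation",
    "AirwayHistory",
    "PatientRecord",
    "TeamRoster",
    "MedAdministration",
    "CaseOutcomes",
    "SurgicalCase",
    "Dataset",
]


class Sex(str, Enum):
    female = "female"
    male = "male"
    other = "other"


class PreopFlag(str, Enum):
    """Preoperative-evaluation checkbox flags that can satisfy a criterion
    without a coded diagnosis."""

    copd = "copd"
    supplemental_o2 = "supplemental_o2"
    lung_transplant = "lung_transplant"
    recent_uri = "recent_uri"
    sleep_apnea = "sleep_apnea"


class Analyte(str, Enum):
    hemoglobin_serum = "hemoglobin_serum"  # g/dL
    other = "other"


class VitalKind(str, Enum):
    spo2 = "spo2"  # percent


class AirwayPlan(str, Enum):
    intubated_general = "intubated_general"
    non_intubated = "non_intubated"


class DelayReason(str, Enum):
    patient_related = "patient_related"
    scheduling = "scheduling"
    staff_related = "staff_related"
    none = "none"


class Disposition(str, Enum):
    pacu = "pacu"
    icu_direct = "icu_direct"
    icu_unplanned_transfer = "icu_unplanned_transfer"
    floor = "floor"


class Drug(str, Enum):
    rocuronium = "rocuronium"
    sugammadex = "sugammadex"
    neostigmine = "neostigmine"
    other = "other"


class MedSource(str, Enum):
    study_pathway = "study_pathway"
    standard_stock = "standard_stock"
    not_applicable = "n/a"


class TeamCategory(str, Enum):
    full_team = "full_team"
    attending_crna = "attending_crna"
    attending_resident = "attending_resident"
    solo_attending = "solo_attending"


class DiagnosisEvent(BaseModel):
    icd10: str = Field(min_length=1)
    onset_date: date
    active_from: Optional[date] = None
    active_to: Optional[date] = None


class LabResult(BaseModel):
    analyte: Analyte
    value: float  # analyte units; g/dL for serum hemoglobin
    collected_at: datetime

    @field_validator("value")
    @classmethod
    def _finite(cls, v: float) -> float:
        if not isfinite(v):
            raise ValueError("lab value must be finite")
        return v


class VitalSample(BaseModel):
    kind: VitalKind = VitalKind.spo2
    value: float = Field(ge=0, le=100)  # percent
    observed_at: datetime


class BmiObservation(BaseModel):
    observed_at: datetime
    value: float = Field(gt=0)  # kg/m^2


class AirwayHistory(BaseModel):
    max_ventilator_hours_pre_admission: float = Field(default=0.0, ge=0)
    tracheostomy_pre_admission: bool = False
    prior_case_max_intubation_attempts: int = Field(default=0, ge=0)


class PatientRecord(BaseModel):
    """Longitudinal clinical facts for one patient."""

    patient_id: str = Field(min_length=1)
    birth_date: date
    sex: Sex = Sex.other
    pregnant_or_lactating: bool = False
    allergies: list[str] = Field(default_factory=list)  # normalized drug names
    diagnoses: list[DiagnosisEvent] = Field(default_factory=list)
    preop_eval_flags: set[PreopFlag] = Field(default_factory=set)
    labs: list[LabResult] = Field(default_factory=list)
    vitals: list[VitalSample] = Field(default_factory=list)
    airway_history: AirwayHistory = Field(default_factory=AirwayHistory)
    bmi_observations: list[BmiObservation] = Field(default_factory=list)
    neuromuscular_disease: bool = False
    gfr_latest: Optional[float] = None  # mL/min/1.73 m^2

    @field_serializer("preop_eval_flags")
    def _ser_flags(self, flags: set[PreopFlag]) -> list[str]:
        return sorted(f.value for f in flags)  # stable serialization order

    @model_validator(mode="after")
    def _sort_facts(self) -> "PatientRecord":
        self.diagnoses.sort(key=lambda d: (d.onset_date, d.icd10))
        self.labs.sort(key=lambda l: (l.collected_at, l.analyte.value, l.value))
        self.vitals.sort(key=lambda v: (v.observed_at, v.value))
        self.bmi_observations.sort(key=lambda b: (b.observed_at, b.value))
        return self


class TeamRoster(BaseModel):
    attending_id: str = Field(min_length=1)
    crna_present: bool = False
    resident_present: bool = False


class MedAdministration(BaseModel):
    drug: Drug
    source: MedSource = MedSource.not_applicable
    administered_at: datetime
    ordered_via_bpa: bool = False

    @model_validator(mode="after")
    def _study_pathway_consistency(self) -> "MedAdministration":
        if self.source == MedSource.study_pathway:
            if self.drug != Drug.sugammadex or not self.ordered_via_bpa:
                raise ValueError(
                    "study_pathway source requires sugammadex ordered via the BPA"
                )
        return self


class CaseOutcomes(BaseModel):
    unexpected_icu_transfer: bool = False
    reintubation: bool = False
    pacu_los_min: Optional[float] = Field(default=None, ge=0)
    min_spo2: Optional[float] = Field(default=None, ge=0, le=100)
    death: bool = False


class SurgicalCase(BaseModel):
    """One anesthetic encounter: schedule, staffing, meds, disposition."""

    case_id: str = Field(min_length=1)
    patient_id: str = Field(min_length=1)
    site: str = Field(min_length=1)
    scheduled_start: datetime
    scheduled_duration_min: int = Field(gt=0)
    service: str = ""
    procedure_name: str = ""
    cpt_codes: list[str] = Field(default_factory=list)
    emergency: bool = False
    airway_plan: AirwayPlan = AirwayPlan.intubated_general
    planned_postop_intubation: bool = False
    asa_status: Optional[int] = Field(default=None, ge=1, le=5)
    staffing: TeamRoster
    delays: set[DelayReason] = Field(default_factory=set)
    meds: list[MedAdministration] = Field(default_factory=list)
    disposition: Disposition = Disposition.pacu
    outcomes: CaseOutcomes = Field(default_factory=CaseOutcomes)

    @field_serializer("delays")
    def _ser_delays(self, delays: set[DelayReason]) -> list[str]:
        return sorted(d.value for d in delays)  # stable serialization order

    @model_validator(mode="after")
    def _consistency(self) -> "SurgicalCase":
        if (
            self.disposition == Disposition.icu_direct
            and self.outcomes.pacu_los_min is not None
        ):
            raise ValueError("pacu_los_min must be absent for direct ICU admissions")
        self.meds.sort(key=lambda m: (m.administered_at, m.drug.value))
        return self


class Dataset(BaseModel):
    """A validated cohort: patients keyed by id plus the case list.

    Construction enforces patient-id uniqueness and referential integrity
    (every case's ``patient_id`` must resolve).
    """

    patients: dict[str, PatientRecord]
    cases: list[SurgicalCase]

    @model_validator(mode="after")
    def _integrity(self) -> "Dataset":
        for pid, patient in self.patients.items():
            if patient.patient_id != pid:
                raise ValueError(f"patient key {pid!r} != record id {patient.patient_id!r}")
        seen_cases: set[str] = set()
        for case in self.cases:
            if case.case_id in seen_cases:
                raise ValueError(f"duplicate case_id {case.case_id!r}")
            seen_cases.add(case.case_id)
            if case.patient_id not in self.patients:
                raise ValueError(
                    f"case {case.case_id!r} references unknown patient {case.patient_id!r}"
                )
        return self

    @classmethod
    def from_lists(
        cls, patients: list[PatientRecord], cases: list[SurgicalCase]
    ) -> "Dataset":
        index: dict[str, PatientRecord] = {}
        for p in patients:
            if p.patient_id in index:
                raise ValueError(f"duplicate patient_id {p.patient_id!r}")
            index[p.patient_id] = p
        return cls(patients=index, cases=cases)
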