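"""Synthetic EHR cohort generator with a ground-truth ledger.

Generation is *constructive*: the latent truth (which criteria and
exclusions each (patient, case) pair satisfies, which team staffed the
case, how the provider will respond) is sampled first, then concrete EHR
facts are emitted that realize that truth exactly — a sampled obstructive
sleep apnea becomes a G47.33 diagnosis or a sleep-apnea preop flag, a
sampled low-SpO2 criterion becomes vital samples inside the 12-hour window
with mean below 95, and so on. Negatives are realized so they do *not*
trigger, including deliberately boundary-adjacent negatives (mean SpO2
exactly 95, duration exactly 120 min, BMI exactly 35 or 40, hemoglobin
exactly 10 g/dL, GFR exactly 30, 24 ventilator hours, a low hemoglobin
just outside the 6-month window) emitted at a configurable rate, so the
strict-inequality and window semantics of the rule engine are exercised.

Provider behavior: each attending has a latent adherence propensity per
team category, drawn once from a team-conditional beta mixture (the solo-
attending default is a two-component mixture, giving the characteristic
bimodal solo distribution). Per-case adherence probability applies
configured covariate effects on the log-odds scale, with covariates
centered at their configured prevalences so team-level marginal adherence
stays at the mixture mean while odds ratios are unchanged.

Determinism: one RNG stream per record type, all spawned from the master
seed, so identical configs produce bitwise-identical serialized output and
adding draws to one stage never perturbs another.

Default prevalences are plausible placeholders for a large academic
perioperative cohort — the true criterion prevalences of any particular
institution are not published; see ``docs/methods.md``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.special import expit, logit

from .criteria import CriterionId, Exclusion, MAJOR_CRITERIA, MINOR_CRITERIA
from .errors import ConfigError
from .io import write_dataset
from .types import (
    AirwayHistory,
    AirwayPlan,
    BmiObservation,
    CaseOutcomes,
    Dataset,
    DelayReason,
    DiagnosisEvent,
    Disposition,
    Drug,
    LabResult,
    MedAdministration,
    MedSource,
    PatientRecord,
    Sex,
    SurgicalCase,
    TeamCategory,
    TeamRoster,
    VitalSample,
)

__all__ = ["BetaMixture", "SimConfig", "Cohort", "generate_cohort",
           "simulate_provider_responses", "simulate_cohort", "write_fixture"]


class BetaMixture(BaseModel):
    """Mixture of beta distributions: list of (weight, alpha, beta)."""

    components: list[tuple[float, float, float]]

    @model_validator(mode="after")
    def _check(self) -> "BetaMixture":
        if not self.components:
            raise ValueError("mixture needs at least one component")
        total = sum(w for w, _, _ in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {total}")
        if any(w < 0 or a <= 0 or b <= 0 for w, a, b in self.components):
            raise ValueError("mixture parameters must be positive")
        return self

    @property
    def mean(self) -> float:
        return sum(w * a / (a + b) for w, a, b in self.components)

    def sample(self, rng: np.random.Generator) -> float:
        weights = [w for w, _, _ in self.components]
        idx = int(rng.choice(len(self.components), p=weights))
        _, a, b = self.components[idx]
        return float(rng.beta(a, b))


# Team adherence-propensity defaults: single betas whose means emulate
# reported stratum adherence in a large perioperative cohort; the solo
# stratum is a two-component mixture producing a bimodal provider
# distribution (clusters of consistently low and consistently high
# adherers).
_DEFAULT_PROPENSITIES: dict[str, BetaMixture] = {
    TeamCategory.full_team.value: BetaMixture(components=[(1.0, 2.2, 1.633)]),
    TeamCategory.attending_crna.value: BetaMixture(components=[(1.0, 3.0, 2.272)]),
    TeamCategory.attending_resident.value: BetaMixture(components=[(1.0, 2.8, 2.523)]),
    TeamCategory.solo_attending.value: BetaMixture(
        components=[(0.628, 1.6, 5.5), (0.372, 5.5, 1.8)]
    ),
}

_DEFAULT_CRITERION_PREVALENCES: dict[str, float] = {
    CriterionId.obstructive_restrictive_lung_disease.value: 0.12,
    CriterionId.acute_respiratory_infection.value: 0.03,
    CriterionId.obstructive_sleep_apnea.value: 0.15,
    CriterionId.low_preop_spo2.value: 0.04,
    CriterionId.airway_pathology_history.value: 0.02,
    CriterionId.bmi_over_40.value: 0.08,
    CriterionId.multiple_intubation_attempts.value: 0.01,
    CriterionId.long_surgery.value: 0.45,
    CriterionId.high_risk_surgical_site.value: 0.20,
    CriterionId.bmi_over_35.value: 0.18,  # inclusive of BMI > 40
    CriterionId.low_hemoglobin.value: 0.06,
}

_DEFAULT_EXCLUSION_PREVALENCES: dict[str, float] = {
    Exclusion.age_lt_18.value: 0.005,
    Exclusion.pregnant_lactating.value: 0.01,
    Exclusion.neuromuscular_disease.value: 0.01,
    Exclusion.gfr_lt_30.value: 0.02,
    Exclusion.sugammadex_allergy.value: 0.002,
    Exclusion.planned_postop_intubation.value: 0.02,
    Exclusion.non_intubated.value: 0.04,
    Exclusion.emergency.value: 0.03,
}

# covariate log-odds effects on adherence (workflow effects dominate)
_DEFAULT_COVARIATE_EFFECTS: dict[str, float] = {
    "long_surgery": 0.30,
    "delay_patient_related": 0.31,
    "delay_scheduling": 0.25,
    "delay_staff_related": -0.545,
    "low_hemoglobin": 0.846,
    "low_preop_spo2": -0.734,
}


class SimConfig(BaseModel):
    """Everything the generator needs; identical configs (including seed)
    yield bitwise-identical serialized cohorts."""

    n_patients: int = Field(default=1000, gt=0)
    seed: int = 0
    criterion_prevalences: dict[str, float] = Field(
        default_factory=lambda: dict(_DEFAULT_CRITERION_PREVALENCES)
    )
    exclusion_prevalences: dict[str, float] = Field(
        default_factory=lambda: dict(_DEFAULT_EXCLUSION_PREVALENCES)
    )
    site_mix: dict[str, float] = Field(
        default_factory=lambda: {"main_campus": 0.55, "west_campus": 0.35, "community": 0.10}
    )
    eligible_sites: list[str] = Field(default_factory=lambda: ["main_campus", "west_campus"])
    # stratum shares for a large academic OR mix
    team_mix: dict[str, float] = Field(
        default_factory=lambda: {
            TeamCategory.full_team.value: 0.084,
            TeamCategory.attending_crna.value: 0.255,
            TeamCategory.attending_resident.value: 0.543,
            TeamCategory.solo_attending.value: 0.118,
        }
    )
    delay_probabilities: dict[str, float] = Field(
        default_factory=lambda: {
            DelayReason.patient_related.value: 0.08,
            DelayReason.scheduling.value: 0.10,
            DelayReason.staff_related.value: 0.06,
        }
    )
    # pacu/icu split chosen so that, conditional on alert firing (which
    # removes planned direct-ICU admissions), unplanned ICU transfers are
    # ~10.3% of alerted cases
    disposition_model: dict[str, float] = Field(
        default_factory=lambda: {
            Disposition.pacu.value: 0.861,
            Disposition.icu_direct.value: 0.04,
            Disposition.icu_unplanned_transfer.value: 0.099,
        }
    )
    rocuronium_probability: float = Field(default=0.686, ge=0, le=1)
    stock_bypass_share: float = Field(default=0.8, ge=0, le=1)
    adherence_propensities: dict[str, BetaMixture] = Field(
        default_factory=lambda: {k: v.model_copy() for k, v in _DEFAULT_PROPENSITIES.items()}
    )
    covariate_effects: dict[str, float] = Field(
        default_factory=lambda: dict(_DEFAULT_COVARIATE_EFFECTS)
    )
    n_attendings: int = Field(default=120, gt=0)
    boundary_negative_rate: float = Field(default=0.15, ge=0, le=1)
    emit_asa: bool = True
    base_date: date = date(2023, 1, 2)
    schedule_span_days: int = Field(default=600, gt=0)

    @model_validator(mode="after")
    def _validate(self) -> "SimConfig":
        for name, mapping in (
            ("criterion_prevalences", self.criterion_prevalences),
            ("exclusion_prevalences", self.exclusion_prevalences),
            ("delay_probabilities", self.delay_probabilities),
        ):
            for key, p in mapping.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"{name}[{key}] = {p} outside [0, 1]")
        missing = set(_DEFAULT_CRITERION_PREVALENCES) - set(self.criterion_prevalences)
        if missing:
            raise ValueError(f"criterion_prevalences missing: {sorted(missing)}")
        p35 = self.criterion_prevalences[CriterionId.bmi_over_35.value]
        p40 = self.criterion_prevalences[CriterionId.bmi_over_40.value]
        if p35 < p40:
            raise ValueError(
                "unsatisfiable config: P(BMI>35) must be >= P(BMI>40) "
                f"(got {p35} < {p40})"
            )
        for name, mix in (("site_mix", self.site_mix), ("team_mix", self.team_mix),
                          ("disposition_model", self.disposition_model)):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {total}")
        unknown_teams = set(self.team_mix) - {t.value for t in TeamCategory}
        if unknown_teams:
            raise ValueError(f"unknown team categories: {sorted(unknown_teams)}")
        for team in self.team_mix:
            if team not in self.adherence_propensities:
                raise ValueError(f"no adherence propensity mixture for team {team!r}")
        return self

    def config_hash(self) -> str:
        return hashlib.sha256(
            self.model_dump_json(exclude_none=False).encode("utf-8")
        ).hexdigest()[:16]


@dataclass
class Cohort:
    """A generated cohort plus its ground-truth ledger (one row per case)."""

    dataset: Dataset
    ledger: pd.DataFrame
    config: SimConfig

    @property
    def patients(self) -> dict[str, PatientRecord]:
        return self.dataset.patients

    @property
    def cases(self) -> list[SurgicalCase]:
        return self.dataset.cases


_OBSTRUCTIVE_CODES = ["J40", "J41.0", "J41.8", "J42", "J43.1", "J43.9", "J44.0",
                      "J44.9", "J45.20", "J45.909", "J47.0", "J84.1", "J84.9", "D86.0"]
_INFECTION_CODES = ["J00", "J06.9", "J09.X2", "J10.1", "J12.9", "J15.9", "J16.8",
                    "J17", "J18.9", "J20.9"]
_DISTRACTOR_CODES = ["I10", "E11.9", "K21.9", "M54.5", "N39.0", "Z98.890",
                     "J41.9", "G47.30", "J22"]  # last three are boundary-adjacent
_OBSTRUCTIVE_FLAGS = ["copd", "supplemental_o2", "lung_transplant"]

_SITE_POSITIVE = [
    ("General Surgery", "Open Gastric Bypass", []),
    ("General Surgery", "Liver segmentectomy", []),
    ("General Surgery", "Whipple pancreas resection", []),
    ("General Surgery", "Hepatectomy, partial", []),
    ("General Surgery", "Laparoscopic Cholecystectomy", ["47562"]),
    ("Thoracic Surgery", "VATS right upper lobe", []),
    ("Thoracic Surgery", "Esophagectomy", []),
    ("Thoracic Surgery", "Pulmonary wedge resection", []),
    ("Thoracic Surgery", "Thoracotomy, exploratory", []),
    ("Head and Neck", "Neck dissection, radical", []),
    ("Head and Neck", "Parotidectomy", []),
    ("Head and Neck", "Mastoidectomy", []),  # one forbidden token only
    ("Bariatric Surgery", "Laparoscopic Sleeve Gastrectomy", ["43775"]),
    ("Bariatric Surgery", "Laparoscopic Roux-En-Y", ["43644"]),
]
_SITE_NEGATIVE = [
    ("Neurosurgery", "Craniotomy for tumor", ["61510"]),
    ("Neurosurgery", "Lumbar laminectomy", []),
    ("General Surgery", "Kidney Transplant", []),
    ("General Surgery", "Inguinal hernia repair", ["49505"]),
    ("Head and Neck", "Tympanomastoidectomy", []),  # both forbidden tokens
    ("Orthopedics", "Total knee arthroplasty", ["27447"]),
    ("Urology", "Robotic prostatectomy", []),
    ("OB/GYN", "Hysterectomy, abdominal", []),
]


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ("bits", "patients", "cases", "providers", "behavior", "outcomes")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def _sample_categorical(rng: np.random.Generator, mix: Mapping[str, float], n: int) -> list[str]:
    keys = list(mix.keys())
    probs = np.array([mix[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(keys), size=n, p=probs)
    return [keys[i] for i in idx]


def generate_cohort(config: SimConfig) -> Cohort:
    """Sample the latent truth and emit patients + cases realizing it.

    Meds and postoperative outcomes are left empty; apply
    :func:`simulate_provider_responses` (or use :func:`simulate_cohort`).
    """
    try:
        config = SimConfig.model_validate(config.model_dump())
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    rngs = _streams(config.seed)
    n = config.n_patients
    bits_rng, pat_rng, case_rng = rngs["bits"], rngs["patients"], rngs["cases"]

    crit = {}
    prev = config.criterion_prevalences
    for cid in (*MAJOR_CRITERIA, *MINOR_CRITERIA):
        if cid in (CriterionId.bmi_over_40, CriterionId.bmi_over_35):
            continue
        crit[cid.value] = bits_rng.random(n) < prev[cid.value]
    u_bmi = bits_rng.random(n)
    p40 = prev[CriterionId.bmi_over_40.value]
    p35 = prev[CriterionId.bmi_over_35.value]
    bmi_cat = np.where(u_bmi < p40, "over_40", np.where(u_bmi < p35, "35_to_40", "under_35"))
    crit[CriterionId.bmi_over_40.value] = bmi_cat == "over_40"
    crit[CriterionId.bmi_over_35.value] = bmi_cat != "under_35"

    excl = {
        name: bits_rng.random(n) < p for name, p in sorted(config.exclusion_prevalences.items())
    }
    sites = _sample_categorical(bits_rng, config.site_mix, n)
    teams = _sample_categorical(bits_rng, config.team_mix, n)
    dispositions = _sample_categorical(bits_rng, config.disposition_model, n)
    delays_bits = {
        name: bits_rng.random(n) < p for name, p in sorted(config.delay_probabilities.items())
    }
    attending_weights = rngs["providers"].dirichlet(np.ones(config.n_attendings))
    attending_idx = bits_rng.choice(config.n_attendings, size=n, p=attending_weights)
    sexes = bits_rng.choice([Sex.female.value, Sex.male.value], size=n)
    asa = bits_rng.choice([1, 2, 3, 4], size=n, p=[0.10, 0.40, 0.40, 0.10])

    eligible_sites = set(config.eligible_sites)
    patients: list[PatientRecord] = []
    cases: list[SurgicalCase] = []
    ledger_rows: list[dict] = []

    for i in range(n):
        pid = f"P{i:06d}"
        cid_str = f"C{i:06d}"
        day = int(case_rng.integers(0, config.schedule_span_days))
        hour = int(case_rng.integers(8, 15))
        minute = int(case_rng.choice([0, 15, 30, 45]))
        start = datetime.combine(config.base_date + timedelta(days=day),
                                 datetime.min.time()).replace(hour=hour, minute=minute)
        boundary = lambda: case_rng.random() < config.boundary_negative_rate  # noqa: E731

        # ----- demographics & exclusions
        if excl[Exclusion.age_lt_18.value][i]:
            age_days = int(pat_rng.integers(12 * 365, 18 * 365 - 10))
            birth = start.date() - timedelta(days=age_days)
        elif boundary():
            # exactly 18 on the day of surgery: not excluded
            try:
                birth = start.date().replace(year=start.year - 18)
            except ValueError:  # Feb 29
                birth = start.date().replace(year=start.year - 18, day=28)
        else:
            birth = start.date() - timedelta(days=int(pat_rng.integers(18 * 366, 90 * 365)))
        if excl[Exclusion.gfr_lt_30.value][i]:
            gfr: Optional[float] = round(float(pat_rng.uniform(8, 29.5)), 1)
        elif pat_rng.random() < 0.2:
            gfr = None
        elif boundary():
            gfr = 30.0
        else:
            gfr = round(float(pat_rng.uniform(31, 120)), 1)
        allergies = ["Sugammadex"] if excl[Exclusion.sugammadex_allergy.value][i] else (
            ["penicillin"] if pat_rng.random() < 0.2 else []
        )

        # ----- inclusion criteria realized as facts
        diagnoses: list[DiagnosisEvent] = []
        flags: set[str] = set()
        labs: list[LabResult] = []
        vitals: list[VitalSample] = []
        bmis: list[BmiObservation] = []

        def dx(code: str, days_back: int) -> None:
            diagnoses.append(
                DiagnosisEvent(icd10=code, onset_date=start.date() - timedelta(days=days_back))
            )

        if crit[CriterionId.obstructive_restrictive_lung_disease.value][i]:
            if pat_rng.random() < 0.7:
                dx(str(pat_rng.choice(_OBSTRUCTIVE_CODES)), int(pat_rng.integers(60, 3000)))
            else:
                flags.add(str(pat_rng.choice(_OBSTRUCTIVE_FLAGS)))
        if crit[CriterionId.acute_respiratory_infection.value][i]:
            if pat_rng.random() < 0.7:
                dx(str(pat_rng.choice(_INFECTION_CODES)), int(pat_rng.integers(0, 30)))
            else:
                flags.add("recent_uri")
        elif boundary():
            # infection code just outside the 30-day window
            dx(str(pat_rng.choice(_INFECTION_CODES)), int(pat_rng.integers(31, 90)))
        if crit[CriterionId.obstructive_sleep_apnea.value][i]:
            if pat_rng.random() < 0.7:
                dx("G47.33", int(pat_rng.integers(30, 3000)))
            else:
                flags.add("sleep_apnea")
        if pat_rng.random() < 0.5:
            dx(str(pat_rng.choice(_DISTRACTOR_CODES)), int(pat_rng.integers(40, 2000)))

        if crit[CriterionId.low_preop_spo2.value][i]:
            k = int(pat_rng.integers(2, 5))
            for _ in range(k):
                vitals.append(VitalSample(
                    value=round(float(pat_rng.uniform(86, 94)), 1),
                    observed_at=start - timedelta(minutes=int(pat_rng.integers(5, 700))),
                ))
        elif pat_rng.random() < 0.5:
            if boundary():
                for _ in range(2):  # mean exactly at the threshold: not met
                    vitals.append(VitalSample(
                        value=95.0,
                        observed_at=start - timedelta(minutes=int(pat_rng.integers(5, 700))),
                    ))
            else:
                for _ in range(int(pat_rng.integers(1, 4))):
                    vitals.append(VitalSample(
                        value=round(float(pat_rng.uniform(96, 100)), 1),
                        observed_at=start - timedelta(minutes=int(pat_rng.integers(5, 700))),
                    ))
            # a low reading outside the 12-hour window must not count
            if pat_rng.random() < 0.3:
                vitals.append(VitalSample(
                    value=round(float(pat_rng.uniform(85, 92)), 1),
                    observed_at=start - timedelta(hours=float(pat_rng.uniform(13, 72))),
                ))

        if crit[CriterionId.airway_pathology_history.value][i]:
            if pat_rng.random() < 0.6:
                airway = AirwayHistory(
                    max_ventilator_hours_pre_admission=round(float(pat_rng.uniform(25, 300)), 1),
                    tracheostomy_pre_admission=bool(pat_rng.random() < 0.3),
                )
            else:
                airway = AirwayHistory(tracheostomy_pre_admission=True)
        else:
            hours = 24.0 if boundary() else round(float(pat_rng.uniform(0, 23.5)), 1)
            airway = AirwayHistory(max_ventilator_hours_pre_admission=hours)
        attempts = (
            int(pat_rng.integers(2, 5))
            if crit[CriterionId.multiple_intubation_attempts.value][i]
            else (1 if boundary() else 0)
        )
        airway = airway.model_copy(update={"prior_case_max_intubation_attempts": attempts})

        cat = bmi_cat[i]
        if cat == "over_40":
            bmi_val = round(float(pat_rng.uniform(40.2, 55)), 1)
        elif cat == "35_to_40":
            bmi_val = round(float(pat_rng.uniform(35.1, 39.9)), 1)
        else:
            bmi_val = 35.0 if boundary() else round(float(pat_rng.uniform(19, 34.9)), 1)
        bmis.append(BmiObservation(
            observed_at=start - timedelta(days=int(pat_rng.integers(0, 20)),
                                          hours=int(pat_rng.integers(1, 12))),
            value=bmi_val,
        ))
        if pat_rng.random() < 0.2:
            # stale earlier observation; the latest one must win
            bmis.append(BmiObservation(
                observed_at=start - timedelta(days=int(pat_rng.integers(90, 400))),
                value=round(float(pat_rng.uniform(19, 50)), 1),
            ))

        if crit[CriterionId.low_hemoglobin.value][i]:
            labs.append(LabResult(
                analyte="hemoglobin_serum",
                value=round(float(pat_rng.uniform(6.5, 9.9)), 1),
                collected_at=start - timedelta(days=int(pat_rng.integers(1, 180))),
            ))
        elif pat_rng.random() < 0.5:
            if boundary():
                choice = pat_rng.random()
                if choice < 0.5:  # exactly 10: not met
                    labs.append(LabResult(
                        analyte="hemoglobin_serum", value=10.0,
                        collected_at=start - timedelta(days=int(pat_rng.integers(1, 180))),
                    ))
                else:  # low but outside the 183-day window
                    labs.append(LabResult(
                        analyte="hemoglobin_serum",
                        value=round(float(pat_rng.uniform(7, 9.5)), 1),
                        collected_at=start - timedelta(days=int(pat_rng.integers(184, 500))),
                    ))
            else:
                labs.append(LabResult(
                    analyte="hemoglobin_serum",
                    value=round(float(pat_rng.uniform(10.5, 16)), 1),
                    collected_at=start - timedelta(days=int(pat_rng.integers(1, 180))),
                ))

        patient = PatientRecord(
            patient_id=pid,
            birth_date=birth,
            sex=sexes[i],
            pregnant_or_lactating=bool(excl[Exclusion.pregnant_lactating.value][i]),
            allergies=allergies,
            diagnoses=diagnoses,
            preop_eval_flags=flags,
            labs=labs,
            vitals=vitals,
            airway_history=airway,
            bmi_observations=bmis,
            neuromuscular_disease=bool(excl[Exclusion.neuromuscular_disease.value][i]),
            gfr_latest=gfr,
        )

        # ----- surgical case
        if crit[CriterionId.long_surgery.value][i]:
            duration = int(case_rng.integers(121, 420))
        else:
            duration = 120 if boundary() else int(case_rng.integers(45, 121))
        if crit[CriterionId.high_risk_surgical_site.value][i]:
            service, name, cpts = _SITE_POSITIVE[int(case_rng.integers(len(_SITE_POSITIVE)))]
        else:
            service, name, cpts = _SITE_NEGATIVE[int(case_rng.integers(len(_SITE_NEGATIVE)))]
        team = TeamCategory(teams[i])
        roster = TeamRoster(
            attending_id=f"A{attending_idx[i]:04d}",
            crna_present=team in (TeamCategory.full_team, TeamCategory.attending_crna),
            resident_present=team in (TeamCategory.full_team, TeamCategory.attending_resident),
        )
        delays = {DelayReason(name_) for name_, arr in delays_bits.items() if arr[i]}
        disposition = Disposition(dispositions[i])
        case = SurgicalCase(
            case_id=cid_str,
            patient_id=pid,
            site=sites[i],
            scheduled_start=start,
            scheduled_duration_min=duration,
            service=service,
            procedure_name=name,
            cpt_codes=list(cpts),
            emergency=bool(excl[Exclusion.emergency.value][i]),
            airway_plan=(
                AirwayPlan.non_intubated
                if excl[Exclusion.non_intubated.value][i]
                else AirwayPlan.intubated_general
            ),
            planned_postop_intubation=bool(excl[Exclusion.planned_postop_intubation.value][i]),
            asa_status=int(asa[i]) if config.emit_asa else None,
            staffing=roster,
            delays=delays or {DelayReason.none},
            disposition=disposition,
        )

        majors = sum(bool(crit[c.value][i]) for c in MAJOR_CRITERIA)
        minors = sum(bool(crit[c.value][i]) for c in MINOR_CRITERIA)
        true_exclusions = sorted(
            [name_ for name_, arr in excl.items() if arr[i]]
            + ([Exclusion.direct_icu_admission.value] if disposition == Disposition.icu_direct else [])
        )
        row = {
            "case_id": cid_str,
            "patient_id": pid,
            "attending_id": roster.attending_id,
            "team": team.value,
            "site": sites[i],
            "site_eligible": sites[i] in eligible_sites,
            "majors": majors,
            "minors": minors,
            "true_eligible": majors >= 1 or minors >= 2,
            "true_exclusions": ";".join(true_exclusions),
            "true_excluded": bool(true_exclusions),
            "disposition": disposition.value,
            "asa": int(asa[i]) if config.emit_asa else None,
        }
        for c in (*MAJOR_CRITERIA, *MINOR_CRITERIA):
            row[f"crit_{c.value}"] = bool(crit[c.value][i])
        for name_, arr in delays_bits.items():
            row[f"delay_{name_}"] = bool(arr[i])
        row["intended_alert"] = (
            row["true_eligible"] and not row["true_excluded"] and row["site_eligible"]
        )
        patients.append(patient)
        cases.append(case)
        ledger_rows.append(row)

    dataset = Dataset.from_lists(patients, cases)
    return Cohort(dataset=dataset, ledger=pd.DataFrame(ledger_rows), config=config)


def _covariate_value(row: Mapping, name: str) -> bool:
    if name.startswith("delay_"):
        return bool(row[name])
    return bool(row[f"crit_{name}"])


def _covariate_prevalence(config: SimConfig, name: str) -> float:
    if name.startswith("delay_"):
        return config.delay_probabilities.get(name.removeprefix("delay_"), 0.0)
    return config.criterion_prevalences[name]


def simulate_provider_responses(cohort: Cohort) -> Cohort:
    """Assign medications and postoperative outcomes per provider behavior.

    Each attending's latent propensity per team category is drawn once; the
    per-case adherence probability applies covariate effects on the
    log-odds scale with prevalence-centered covariates. Non-adherent
    responses split between a standard-stock sugammadex bypass and no study
    drug per ``stock_bypass_share``. Mutates and returns the cohort.
    """
    config = cohort.config
    rngs = _streams(config.seed)
    prov_rng, beh_rng, out_rng = rngs["providers"], rngs["behavior"], rngs["outcomes"]
    prov_rng.dirichlet(np.ones(config.n_attendings))  # skip draw used at generation
    propensity: dict[tuple[str, str], float] = {}
    for a in range(config.n_attendings):
        for team in sorted(config.team_mix):
            propensity[(f"A{a:04d}", team)] = config.adherence_propensities[team].sample(prov_rng)

    cases_by_id = {c.case_id: c for c in cohort.cases}
    extra_cols: dict[str, list] = {
        "propensity": [], "p_adhere": [], "intended_adherent": [], "rocuronium": []
    }
    for row in cohort.ledger.to_dict("records"):
        case = cases_by_id[row["case_id"]]
        start = case.scheduled_start
        end = start + timedelta(minutes=case.scheduled_duration_min)
        prop = propensity[(row["attending_id"], row["team"])]
        eta = logit(min(max(prop, 1e-9), 1 - 1e-9))
        for cov, beta in config.covariate_effects.items():
            eta += beta * (float(_covariate_value(row, cov)) - _covariate_prevalence(config, cov))
        p_adhere = float(expit(eta))
        rocuronium = bool(beh_rng.random() < config.rocuronium_probability)
        meds: list[MedAdministration] = []
        if rocuronium:
            meds.append(MedAdministration(
                drug=Drug.rocuronium, source=MedSource.not_applicable,
                administered_at=start + timedelta(minutes=15),
            ))
        adherent = False
        if row["intended_alert"]:
            adherent = bool(beh_rng.random() < p_adhere)
            if adherent:
                meds.append(MedAdministration(
                    drug=Drug.sugammadex, source=MedSource.study_pathway,
                    administered_at=end - timedelta(minutes=10), ordered_via_bpa=True,
                ))
            elif beh_rng.random() < config.stock_bypass_share:
                meds.append(MedAdministration(
                    drug=Drug.sugammadex, source=MedSource.standard_stock,
                    administered_at=end - timedelta(minutes=10),
                ))
            elif beh_rng.random() < 0.5:
                meds.append(MedAdministration(
                    drug=Drug.neostigmine, source=MedSource.standard_stock,
                    administered_at=end - timedelta(minutes=10),
                ))
        elif rocuronium and beh_rng.random() < 0.3:
            meds.append(MedAdministration(
                drug=Drug.sugammadex, source=MedSource.standard_stock,
                administered_at=end - timedelta(minutes=10),
            ))
        case.meds = sorted(meds, key=lambda m: (m.administered_at, m.drug.value))
        case.outcomes = CaseOutcomes(
            unexpected_icu_transfer=case.disposition == Disposition.icu_unplanned_transfer,
            reintubation=bool(out_rng.random() < 0.005),
            pacu_los_min=(
                None
                if case.disposition == Disposition.icu_direct
                else round(float(out_rng.lognormal(4.5, 0.4)), 1)
            ),
            min_spo2=round(float(np.clip(out_rng.normal(93.5, 3.0), 70, 100)), 1),
            death=bool(out_rng.random() < 0.0012),
        )
        extra_cols["propensity"].append(prop)
        extra_cols["p_adhere"].append(p_adhere)
        extra_cols["intended_adherent"].append(adherent)
        extra_cols["rocuronium"].append(rocuronium)
    for col, values in extra_cols.items():
        cohort.ledger[col] = values
    return cohort


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate a cohort and simulate provider responses in one call."""
    return simulate_provider_responses(generate_cohort(config))


def write_fixture(directory: str | Path, cohort: Cohort, format: str = "jsonl") -> None:
    """Write the cohort dataset, the ground-truth ledger, and the embedded
    config (with its seed) so the fixture can be regenerated exactly."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_dataset(directory, cohort.dataset, format=format)
    ledger = cohort.ledger.copy()
    (directory / "ground_truth.csv").write_text(
        ledger.to_csv(index=False, lineterminator="\n"), encoding="utf-8"
    )
    (directory / "sim_config.json").write_text(
        cohort.config.model_dump_json(indent=2) + "\n", encoding="utf-8"
    )
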