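"""Readers and writers for the tabular interchange formats.

Two formats are supported:

* ``jsonl`` — one record per line: ``patients.jsonl`` and ``cases.jsonl``
  with nested fact lists (the canonical format; lossless and compact);
* ``csv`` — RFC-4180, UTF-8, header row required, normalized into seven
  tables: ``patients.csv``, ``diagnoses.csv``, ``labs.csv``, ``vitals.csv``,
  ``bmi_observations.csv``, ``cases.csv``, ``meds.csv``. Multi-valued
  fields (allergies, preop flags, CPT codes, delays) are semicolon-joined
  and therefore must not contain ``;``.

Timestamps are written as ISO-8601 at second resolution, dates as ISO
calendar dates, floats via ``repr`` so numeric round-trips are exact.
Readers validate every row, report per-row diagnostics, and fail hard on
referential breaks (a case naming an unknown patient). The full column
dictionary ships in ``docs/data_dictionary.md``.
"""

from __future__ import annotations

import csv
import json
from datetime import date, datetime
from pathlib import Path
from typing import Any, Iterable

from pydantic import ValidationError

from .errors import DataValidationError
from .types import (
    AirwayHistory,
    BmiObservation,
    CaseOutcomes,
    Dataset,
    DiagnosisEvent,
    LabResult,
    MedAdministration,
    PatientRecord,
    SurgicalCase,
    TeamRoster,
    VitalSample,
)

__all__ = ["read_dataset", "write_dataset", "FORMATS"]

FORMATS = ("jsonl", "csv")

_CSV_FILES = (
    "patients.csv",
    "diagnoses.csv",
    "labs.csv",
    "vitals.csv",
    "bmi_observations.csv",
    "cases.csv",
    "meds.csv",
)

_PATIENT_COLUMNS = [
    "patient_id", "birth_date", "sex", "pregnant_or_lactating", "allergies",
    "preop_eval_flags", "neuromuscular_disease", "gfr_latest",
    "vent_hours_pre_admission", "tracheostomy_pre_admission",
    "prior_case_max_intubation_attempts",
]
_CASE_COLUMNS = [
    "case_id", "patient_id", "site", "scheduled_start", "scheduled_duration_min",
    "service", "procedure_name", "cpt_codes", "emergency", "airway_plan",
    "planned_postop_intubation", "asa_status", "attending_id", "crna_present",
    "resident_present", "delays", "disposition", "unexpected_icu_transfer",
    "reintubation", "pacu_los_min", "min_spo2", "death",
]


def _jsonable(value: Any) -> Any:
    if isinstance(value, dict):
        return {k: _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    if isinstance(value, (set, frozenset)):
        return sorted(_jsonable(v) for v in value)
    if isinstance(value, (datetime, date)):
        return value.isoformat()
    return value


def _dump_line(model: Any) -> str:
    return json.dumps(_jsonable(model.model_dump(mode="json")), sort_keys=True)


def _fmt(value: Any) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    if isinstance(value, (datetime, date)):
        return value.isoformat()
    return str(value)


def _join(values: Iterable[str]) -> str:
    vals = list(values)
    for v in vals:
        if ";" in v:
            raise DataValidationError(f"multi-valued field entry contains ';': {v!r}")
    return ";".join(vals)


def _split(text: str) -> list[str]:
    return [t for t in text.split(";") if t]


def _parse_bool(text: str, where: str) -> bool:
    if text == "true":
        return True
    if text == "false":
        return False
    raise ValueError(f"{where}: expected 'true'/'false', got {text!r}")


def write_dataset(directory: str | Path, dataset: Dataset, format: str = "jsonl") -> None:
    """Serialize a cohort to ``directory`` in the given format."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if format == "jsonl":
        _write_jsonl(directory, dataset)
    elif format == "csv":
        _write_csv(directory, dataset)
    else:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")


def read_dataset(directory: str | Path, format: str = "jsonl") -> Dataset:
    """Load and validate a cohort; returns a referentially intact Dataset."""
    directory = Path(directory)
    if format == "jsonl":
        patients, cases = _read_jsonl(directory)
    elif format == "csv":
        patients, cases = _read_csv(directory)
    else:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    try:
        return Dataset.from_lists(patients, cases)
    except (ValidationError, ValueError) as exc:
        raise DataValidationError(f"referential integrity violated: {exc}") from exc


# ---------------------------------------------------------------- JSONL


def _write_jsonl(directory: Path, dataset: Dataset) -> None:
    with open(directory / "patients.jsonl", "w", encoding="utf-8", newline="\n") as fh:
        for pid in sorted(dataset.patients):
            fh.write(_dump_line(dataset.patients[pid]) + "\n")
    with open(directory / "cases.jsonl", "w", encoding="utf-8", newline="\n") as fh:
        for case in dataset.cases:
            fh.write(_dump_line(case) + "\n")


def _read_jsonl(directory: Path) -> tuple[list[PatientRecord], list[SurgicalCase]]:
    errors: list[str] = []

    def load(path: Path, model: type) -> list:
        if not path.exists():
            raise DataValidationError(f"missing input file: {path}")
        records = []
        for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
            if not line.strip():
                continue
            try:
                records.append(model.model_validate_json(line))
            except (ValidationError, ValueError) as exc:
                errors.append(f"{path.name}:{lineno}: {exc}")
        return records

    patients = load(directory / "patients.jsonl", PatientRecord)
    cases = load(directory / "cases.jsonl", SurgicalCase)
    if errors:
        raise DataValidationError(
            f"{len(errors)} invalid rows while reading {directory}", diagnostics=errors
        )
    return patients, cases


# ------------------------------------------------------------------ CSV


def _write_rows(path: Path, columns: list[str], rows: list[list[str]]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(columns)
        writer.writerows(rows)


def _write_csv(directory: Path, dataset: Dataset) -> None:
    patient_rows, dx_rows, lab_rows, vital_rows, bmi_rows = [], [], [], [], []
    for pid in sorted(dataset.patients):
        p = dataset.patients[pid]
        patient_rows.append([
            p.patient_id, _fmt(p.birth_date), p.sex.value, _fmt(p.pregnant_or_lactating),
            _join(p.allergies), _join(sorted(f.value for f in p.preop_eval_flags)),
            _fmt(p.neuromuscular_disease), _fmt(p.gfr_latest),
            _fmt(p.airway_history.max_ventilator_hours_pre_admission),
            _fmt(p.airway_history.tracheostomy_pre_admission),
            _fmt(p.airway_history.prior_case_max_intubation_attempts),
        ])
        dx_rows += [[pid, d.icd10, _fmt(d.onset_date)] for d in p.diagnoses]
        lab_rows += [[pid, l.analyte.value, _fmt(l.value), _fmt(l.collected_at)] for l in p.labs]
        vital_rows += [[pid, v.kind.value, _fmt(v.value), _fmt(v.observed_at)] for v in p.vitals]
        bmi_rows += [[pid, _fmt(b.observed_at), _fmt(b.value)] for b in p.bmi_observations]
    case_rows, med_rows = [], []
    for c in dataset.cases:
        o = c.outcomes
        case_rows.append([
            c.case_id, c.patient_id, c.site, _fmt(c.scheduled_start),
            _fmt(c.scheduled_duration_min), c.service, c.procedure_name,
            _join(c.cpt_codes), _fmt(c.emergency), c.airway_plan.value,
            _fmt(c.planned_postop_intubation), _fmt(c.asa_status),
            c.staffing.attending_id, _fmt(c.staffing.crna_present),
            _fmt(c.staffing.resident_present),
            _join(sorted(d.value for d in c.delays)), c.disposition.value,
            _fmt(o.unexpected_icu_transfer), _fmt(o.reintubation),
            _fmt(o.pacu_los_min), _fmt(o.min_spo2), _fmt(o.death),
        ])
        med_rows += [
            [c.case_id, m.drug.value, m.source.value, _fmt(m.administered_at),
             _fmt(m.ordered_via_bpa)]
            for m in c.meds
        ]
    _write_rows(directory / "patients.csv", _PATIENT_COLUMNS, patient_rows)
    _write_rows(directory / "diagnoses.csv", ["patient_id", "icd10", "onset_date"], dx_rows)
    _write_rows(directory / "labs.csv", ["patient_id", "analyte", "value", "collected_at"], lab_rows)
    _write_rows(directory / "vitals.csv", ["patient_id", "kind", "value", "observed_at"], vital_rows)
    _write_rows(directory / "bmi_observations.csv", ["patient_id", "observed_at", "value"], bmi_rows)
    _write_rows(directory / "cases.csv", _CASE_COLUMNS, case_rows)
    _write_rows(
        directory / "meds.csv",
        ["case_id", "drug", "source", "administered_at", "ordered_via_bpa"],
        med_rows,
    )


def _read_table(path: Path, required: list[str], errors: list[str]) -> list[dict[str, str]]:
    if not path.exists():
        raise DataValidationError(f"missing input file: {path}")
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in required if c not in header]
        if missing:
            raise DataValidationError(f"{path.name}: missing required columns {missing}")
        rows = []
        for i, row in enumerate(reader, 2):
            if any(v is None for v in row.values()):
                errors.append(f"{path.name}:{i}: short row")
                continue
            rows.append(row)
        return rows


def _read_csv(directory: Path) -> tuple[list[PatientRecord], list[SurgicalCase]]:
    errors: list[str] = []
    p_rows = _read_table(directory / "patients.csv", _PATIENT_COLUMNS, errors)
    dx_rows = _read_table(directory / "diagnoses.csv", ["patient_id", "icd10", "onset_date"], errors)
    lab_rows = _read_table(directory / "labs.csv", ["patient_id", "analyte", "value", "collected_at"], errors)
    vital_rows = _read_table(directory / "vitals.csv", ["patient_id", "kind", "value", "observed_at"], errors)
    bmi_rows = _read_table(directory / "bmi_observations.csv", ["patient_id", "observed_at", "value"], errors)
    c_rows = _read_table(directory / "cases.csv", _CASE_COLUMNS, errors)
    med_rows = _read_table(
        directory / "meds.csv", ["case_id", "drug", "source", "administered_at", "ordered_via_bpa"], errors
    )

    facts: dict[str, dict[str, list]] = {}

    def facts_for(pid: str) -> dict[str, list]:
        return facts.setdefault(pid, {"dx": [], "labs": [], "vitals": [], "bmi": []})

    for i, r in enumerate(dx_rows, 2):
        try:
            facts_for(r["patient_id"])["dx"].append(
                DiagnosisEvent(icd10=r["icd10"], onset_date=r["onset_date"])
            )
        except (ValidationError, ValueError) as exc:
            errors.append(f"diagnoses.csv:{i}: {exc}")
    for i, r in enumerate(lab_rows, 2):
        try:
            facts_for(r["patient_id"])["labs"].append(
                LabResult(analyte=r["analyte"], value=float(r["value"]), collected_at=r["collected_at"])
            )
        except (ValidationError, ValueError) as exc:
            errors.append(f"labs.csv:{i}: {exc}")
    for i, r in enumerate(vital_rows, 2):
        try:
            facts_for(r["patient_id"])["vitals"].append(
                VitalSample(kind=r["kind"], value=float(r["value"]), observed_at=r["observed_at"])
            )
        except (ValidationError, ValueError) as exc:
            errors.append(f"vitals.csv:{i}: {exc}")
    for i, r in enumerate(bmi_rows, 2):
        try:
            facts_for(r["patient_id"])["bmi"].append(
                BmiObservation(observed_at=r["observed_at"], value=float(r["value"]))
            )
        except (ValidationError, ValueError) as exc:
            errors.append(f"bmi_observations.csv:{i}: {exc}")

    patients: list[PatientRecord] = []
    for i, r in enumerate(p_rows, 2):
        try:
            pid = r["patient_id"]
            f = facts_for(pid)
            patients.append(
                PatientRecord(
                    patient_id=pid,
                    birth_date=r["birth_date"],
                    sex=r["sex"],
                    pregnant_or_lactating=_parse_bool(r["pregnant_or_lactating"], "pregnant_or_lactating"),
                    allergies=_split(r["allergies"]),
                    preop_eval_flags=set(_split(r["preop_eval_flags"])),
                    neuromuscular_disease=_parse_bool(r["neuromuscular_disease"], "neuromuscular_disease"),
                    gfr_latest=float(r["gfr_latest"]) if r["gfr_latest"] else None,
                    airway_history=AirwayHistory(
                        max_ventilator_hours_pre_admission=float(r["vent_hours_pre_admission"]),
                        tracheostomy_pre_admission=_parse_bool(
                            r["tracheostomy_pre_admission"], "tracheostomy_pre_admission"
                        ),
                        prior_case_max_intubation_attempts=int(r["prior_case_max_intubation_attempts"]),
                    ),
                    diagnoses=f["dx"],
                    labs=f["labs"],
                    vitals=f["vitals"],
                    bmi_observations=f["bmi"],
                )
            )
        except (ValidationError, ValueError) as exc:
            errors.append(f"patients.csv:{i}: {exc}")

    meds_by_case: dict[str, list[MedAdministration]] = {}
    for i, r in enumerate(med_rows, 2):
        try:
            meds_by_case.setdefault(r["case_id"], []).append(
                MedAdministration(
                    drug=r["drug"],
                    source=r["source"],
                    administered_at=r["administered_at"],
                    ordered_via_bpa=_parse_bool(r["ordered_via_bpa"], "ordered_via_bpa"),
                )
            )
        except (ValidationError, ValueError) as exc:
            errors.append(f"meds.csv:{i}: {exc}")

    cases: list[SurgicalCase] = []
    for i, r in enumerate(c_rows, 2):
        try:
            cases.append(
                SurgicalCase(
                    case_id=r["case_id"],
                    patient_id=r["patient_id"],
                    site=r["site"],
                    scheduled_start=r["scheduled_start"],
                    scheduled_duration_min=int(r["scheduled_duration_min"]),
                    service=r["service"],
                    procedure_name=r["procedure_name"],
                    cpt_codes=_split(r["cpt_codes"]),
                    emergency=_parse_bool(r["emergency"], "emergency"),
                    airway_plan=r["airway_plan"],
                    planned_postop_intubation=_parse_bool(
                        r["planned_postop_intubation"], "planned_postop_intubation"
                    ),
                    asa_status=int(r["asa_status"]) if r["asa_status"] else None,
                    staffing=TeamRoster(
                        attending_id=r["attending_id"],
                        crna_present=_parse_bool(r["crna_present"], "crna_present"),
                        resident_present=_parse_bool(r["resident_present"], "resident_present"),
                    ),
                    delays=set(_split(r["delays"])),
                    meds=meds_by_case.get(r["case_id"], []),
                    disposition=r["disposition"],
                    outcomes=CaseOutcomes(
                        unexpected_icu_transfer=_parse_bool(
                            r["unexpected_icu_transfer"], "unexpected_icu_transfer"
                        ),
                        reintubation=_parse_bool(r["reintubation"], "reintubation"),
                        pacu_los_min=float(r["pacu_los_min"]) if r["pacu_los_min"] else None,
                        min_spo2=float(r["min_spo2"]) if r["min_spo2"] else None,
                        death=_parse_bool(r["death"], "death"),
                    ),
                )
            )
        except (ValidationError, ValueError) as exc:
            errors.append(f"cases.csv:{i}: {exc}")

    if errors:
        raise DataValidationError(
            f"{len(errors)} invalid rows while reading {directory}", diagnostics=errors
        )
    return patients, cases
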