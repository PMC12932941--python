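"""Deliberately naive, independent re-implementation of the eligibility
phenotype, used as an oracle for engine-equivalence tests.

This module intentionally shares no code with the package's criteria
engine: code-set membership is decided by explicit per-token logic written
out longhand, every rule re-reads the raw facts, and the whole verdict is
computed in one flat function. Keep it dumb and obvious.
"""

from datetime import timedelta

# Table of criterion code tokens, written out independently of the package
# resource file.
OBSTRUCTIVE_TOKENS = ["J40", "J41-J41.8", "J42", "J43-J43.9", "J44-J44.9",
                      "J45", "J47-J47.9", "J84.1", "J84.9", "D86"]
INFECTION_TOKENS = ["J00", "J06-J06.9", "J09", "J09.x", "J10-J10.89", "J12-J12.9",
                    "J15-J15.9", "J16-J16.8", "J17", "J18-J18.9", "J20-J20.9"]
OSA_TOKENS = ["G47.33"]


def norm(code):
    return code.strip().upper().replace(".", "")


def in_token(code, token):
    code = norm(code)
    if "-" in token:
        lo, hi = (norm(p) for p in token.split("-"))
        if code[:3] != lo[:3]:
            return False
        return code >= lo and (code <= hi or code.startswith(hi))
    if token.upper().endswith(".X"):
        token = token[:-2]
    return code.startswith(norm(token))


def in_set(code, tokens):
    return any(in_token(code, t) for t in tokens)


def naive_inclusion(patient, case):
    """Return (majors_met, minors_met, included) by re-reading every fact."""
    start = case.scheduled_start
    flags = {f.value for f in patient.preop_eval_flags}

    obstructive = any(
        in_set(d.icd10, OBSTRUCTIVE_TOKENS)
        for d in patient.diagnoses
        if d.onset_date <= start.date()
    ) or bool(flags & {"copd", "supplemental_o2", "lung_transplant"})

    infection = any(
        in_set(d.icd10, INFECTION_TOKENS)
        for d in patient.diagnoses
        if start.date() - timedelta(days=30) <= d.onset_date <= start.date()
    ) or ("recent_uri" in flags)

    osa = any(
        in_set(d.icd10, OSA_TOKENS)
        for d in patient.diagnoses
        if d.onset_date <= start.date()
    ) or ("sleep_apnea" in flags)

    window_vals = [
        v.value
        for v in patient.vitals
        if v.kind.value == "spo2" and start - timedelta(hours=12) < v.observed_at <= start
    ]
    low_spo2 = bool(window_vals) and (sum(window_vals) / len(window_vals) < 95)

    airway = (
        patient.airway_history.max_ventilator_hours_pre_admission > 24
        or patient.airway_history.tracheostomy_pre_admission
    )

    bmis = sorted(
        [b for b in patient.bmi_observations if b.observed_at <= start],
        key=lambda b: b.observed_at,
    )
    latest_bmi = bmis[-1].value if bmis else None
    bmi40 = latest_bmi is not None and latest_bmi > 40
    bmi35 = latest_bmi is not None and latest_bmi > 35

    attempts = patient.airway_history.prior_case_max_intubation_attempts > 1
    long_surgery = case.scheduled_duration_min > 120
    hemoglobin = any(
        lab.analyte.value == "hemoglobin_serum"
        and lab.value < 10
        and start - timedelta(days=183) < lab.collected_at <= start
        for lab in patient.labs
    )

    site = naive_surgical_site(case)

    majors = sum([obstructive, infection, osa, low_spo2, airway, bmi40])
    minors = sum([attempts, long_surgery, site, bmi35, hemoglobin])
    return majors, minors, (majors >= 1 or minors >= 2)


def naive_surgical_site(case):
    name = case.procedure_name.lower()
    if case.service == "Neurosurgery":
        return False
    if "transplant" in name:
        return False
    ok = False
    if case.service == "General Surgery":
        for tok in ["gastric", "liver", "pancreas", "hepat", "chole"]:
            if tok in name:
                ok = True
    if case.service == "Thoracic Surgery":
        for tok in ["pulm", "resection", "esoph", "vats", "lobe", "thoracotomy"]:
            if tok in name:
                ok = True
    if case.service == "Head and Neck":
        if not ("mastoid" in name and "tympano" in name):
            ok = True
    for cpt in case.cpt_codes:
        if cpt in ("43775", "47562", "43644", "43774"):
            ok = True
    return ok


def naive_exclusions(patient, case):
    start = case.scheduled_start.date()
    out = set()
    bd = patient.birth_date
    age = start.year - bd.year - ((start.month, start.day) < (bd.month, bd.day))
    if age < 18:
        out.add("age_lt_18")
    if patient.pregnant_or_lactating:
        out.add("pregnant_lactating")
    if patient.neuromuscular_disease:
        out.add("neuromuscular_disease")
    if patient.gfr_latest is not None and patient.gfr_latest < 30:
        out.add("gfr_lt_30")
    if any(a.strip().lower() == "sugammadex" for a in patient.allergies):
        out.add("sugammadex_allergy")
    if case.planned_postop_intubation:
        out.add("planned_postop_intubation")
    if case.disposition.value == "icu_direct":
        out.add("direct_icu_admission")
    if case.airway_plan.value == "non_intubated":
        out.add("non_intubated")
    if case.emergency:
        out.add("emergency")
    return out
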