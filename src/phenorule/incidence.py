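"""Incident-case identification.

Only newly diagnosed, hospitalized patients are eligible for chart-review
validation: a case is *incident* when its index diagnosis follows a
disease-record-free washout (default one year) and the patient was either
admitted at the initial diagnosis or admitted within one month of an
outpatient diagnosis.  Non-hospitalized patients are excluded.

Semantics. The *index date* is the date the composite algorithm's conditions
are first met (multiplicity thresholds included); *disease evidence* for the
washout and for the initial-diagnosis rule is any encounter, from any
source, matching any component's matcher at threshold one — a single prior
outpatient code is disqualifying history even if no component it belongs to
is satisfied.  With single-record components index and first evidence
coincide, so a patient with exactly one matching encounter can never fail
washout.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass

from .errors import DataError
from .model import ADMISSION_SOURCES, PatientRecord, StudyWindow
from .rules import CompositeAlgorithm, evaluate_composite

__all__ = [
    "IncidenceReason",
    "IncidenceDecision",
    "first_diagnosis_date",
    "classify_incidence",
]


class IncidenceReason(str, enum.Enum):
    ADMITTED_AT_INITIAL_DIAGNOSIS = "admitted_at_initial_diagnosis"
    ADMITTED_WITHIN_MONTH_OF_OUTPATIENT = "admitted_within_month_of_outpatient"
    PRIOR_HISTORY_IN_WASHOUT = "prior_history_in_washout"
    NOT_HOSPITALIZED = "not_hospitalized"


INCIDENT_REASONS = frozenset(
    {
        IncidenceReason.ADMITTED_AT_INITIAL_DIAGNOSIS,
        IncidenceReason.ADMITTED_WITHIN_MONTH_OF_OUTPATIENT,
    }
)


@dataclass(frozen=True)
class IncidenceDecision:
    patient_id: str
    index_date: dt.date
    incident: bool
    reason: IncidenceReason

    def __post_init__(self):
        if self.incident != (self.reason in INCIDENT_REASONS):
            raise DataError(
                f"incident={self.incident} inconsistent with reason {self.reason}"
            )


def _evidence_encounters(patient: PatientRecord, algorithm: CompositeAlgorithm):
    """Encounters carrying disease evidence: any component matcher (with its
    conjunct) holds, irrespective of source and multiplicity."""
    return [
        e
        for e in patient.encounters
        if any(c.matches_encounter(e, ignore_source=True) for c in algorithm.components)
    ]


def first_diagnosis_date(patient: PatientRecord, algorithm: CompositeAlgorithm):
    """Earliest date of any disease-evidence encounter, or None.

    History detection deliberately ignores multiplicity thresholds: the first
    single matching record marks the initial diagnosis.
    """
    evidence = _evidence_encounters(patient, algorithm)
    return min((e.date for e in evidence), default=None)


def classify_incidence(
    patient: PatientRecord,
    algorithm: CompositeAlgorithm,
    window: StudyWindow,
    strict_washout: bool = False,
    any_admission: bool = False,
) -> IncidenceDecision:
    """Classify a matching patient as incident or not, with a reason.

    Checks, in order: (1) washout — any evidence record in the
    ``washout_days`` before the index date (closed at the far end: a record
    exactly ``washout_days`` before index disqualifies) makes the patient
    prevalent; with ``strict_washout`` the patient must additionally have
    been registered at least ``washout_days`` before index; (2) admission at
    initial diagnosis — an admission-type record (admission, inpatient, or
    discharge) among the earliest evidence encounters; (3) admission linkage —
    first evidence ambulatory and an admission-type record within
    ``admission_link_days`` after it (days 1..30 inclusive by default); by
    default the linked admission must itself carry disease evidence,
    ``any_admission`` relaxes this to any admission-type encounter.
    Otherwise the patient is not hospitalized and not incident.

    Raises :class:`DataError` if the patient has no matching encounter.
    """
    evidence = _evidence_encounters(patient, algorithm)
    if not evidence:
        raise DataError(
            f"patient {patient.patient_id!r} has no encounter matching "
            f"{algorithm.disease!r}; classify_incidence requires at least one"
        )
    flag = evaluate_composite(algorithm, patient)
    index_date = flag.first_flag_date if flag.flagged else evidence[0].date

    def decision(reason):
        return IncidenceDecision(
            patient.patient_id, index_date, reason in INCIDENT_REASONS, reason
        )

    washout_start = index_date - dt.timedelta(days=window.washout_days)
    if any(washout_start <= e.date < index_date for e in evidence):
        return decision(IncidenceReason.PRIOR_HISTORY_IN_WASHOUT)
    if strict_washout:
        reg = patient.registration_date
        if reg is None or (index_date - reg).days < window.washout_days:
            return decision(IncidenceReason.PRIOR_HISTORY_IN_WASHOUT)

    first_date = evidence[0].date
    first_day_sources = {e.source for e in evidence if e.date == first_date}
    if first_day_sources & ADMISSION_SOURCES:
        return decision(IncidenceReason.ADMITTED_AT_INITIAL_DIAGNOSIS)

    candidates = patient.encounters if any_admission else evidence
    for e in candidates:
        if e.source in ADMISSION_SOURCES and 1 <= (e.date - first_date).days <= window.admission_link_days:
            return decision(IncidenceReason.ADMITTED_WITHIN_MONTH_OF_OUTPATIENT)
    return decision(IncidenceReason.NOT_HOSPITALIZED)
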