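"""Domain model for EHR registry and encounter data.

A *cohort* is a collection of :class:`PatientRecord` objects, each carrying a
registration window and an ordered stream of :class:`Encounter` diagnosis
records drawn from the five routine record sources (outpatient, emergency,
admission, discharge, inpatient).  Raw exports arrive as delimited text or
line-delimited JSON in arbitrary dialects; a :class:`ColumnMapping` maps them
onto the canonical fields.

All dates are calendar dates (ISO-8601 in I/O); the model operates at day
granularity throughout.
"""

from __future__ import annotations

import enum
import json
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import ConfigError, DataError

__all__ = [
    "Source",
    "Encounter",
    "PatientRecord",
    "StudyWindow",
    "ColumnMapping",
    "LoadReport",
    "load_cohort",
    "apply_cohort_filters",
    "cohort_to_frames",
    "write_cohort",
    "load_cohort_config",
]


class Source(str, enum.Enum):
    """The five routine EHR record sources searched for diagnoses."""

    OUTPATIENT = "outpatient"
    EMERGENCY = "emergency"
    ADMISSION = "admission"
    DISCHARGE = "discharge"
    INPATIENT = "inpatient"

    @classmethod
    def coerce(cls, value: "str | Source") -> "Source":
        if isinstance(value, Source):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise DataError(
                f"unknown encounter source {value!r}; expected one of "
                f"{[s.value for s in cls]}"
            ) from None


#: Sources documenting a (completed) hospital admission.  Discharge records
#: are included because they document a finished inpatient stay.
ADMISSION_SOURCES = frozenset({Source.ADMISSION, Source.INPATIENT, Source.DISCHARGE})

#: Ambulatory sources eligible for the admission-linkage rule.
AMBULATORY_SOURCES = frozenset({Source.OUTPATIENT, Source.EMERGENCY})


@dataclass(frozen=True, order=True)
class Encounter:
    """A single diagnosis record.

    ``diagnosis_text`` may contain Chinese clinical terms; ``icd_codes`` holds
    zero or more ICD-10 code strings.  A record may lack one of the two but
    not both.
    """

    patient_id: str
    source: Source
    date: dt.date
    diagnosis_text: str = ""
    icd_codes: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "source", Source.coerce(self.source))
        codes = frozenset(c.strip() for c in self.icd_codes if c and c.strip())
        object.__setattr__(self, "icd_codes", codes)
        if not self.diagnosis_text and not codes:
            raise DataError(
                f"encounter for {self.patient_id!r} on {self.date} has neither "
                "diagnosis text nor ICD codes"
            )


@dataclass
class PatientRecord:
    """A resident: registration window plus encounter stream.

    ``registration_date`` may be absent in raw extracts (such patients are
    excluded by :func:`apply_cohort_filters`).  ``death_date`` only truncates
    observation; no mortality modelling is done.  Encounters are kept sorted
    by date ascending.
    """

    patient_id: str
    registration_date: dt.date | None = None
    death_date: dt.date | None = None
    encounters: list = field(default_factory=list)

    def __post_init__(self):
        self.encounters = sorted(self.encounters, key=lambda e: (e.date, e.source.value))
        if (
            self.registration_date is not None
            and self.death_date is not None
            and self.death_date < self.registration_date
        ):
            raise DataError(
                f"patient {self.patient_id!r}: death date {self.death_date} "
                f"precedes registration date {self.registration_date}"
            )


@dataclass(frozen=True)
class StudyWindow:
    """Observation window and the two day-granular epidemiological constants.

    ``washout_days`` is the disease-record-free lookback required before an
    index diagnosis counts as incident (default one year = 365 days);
    ``admission_link_days`` is the maximum gap between an outpatient diagnosis
    and a linked hospital admission (default one month = 30 days).
    """

    study_start: dt.date
    study_end: dt.date
    washout_days: int = 365
    admission_link_days: int = 30

    def __post_init__(self):
        if self.study_start >= self.study_end:
            raise ConfigError("study_start must precede study_end")
        if self.washout_days <= 0 or self.admission_link_days <= 0:
            raise ConfigError("washout_days and admission_link_days must be positive")

    def contains(self, date: dt.date) -> bool:
        return self.study_start <= date <= self.study_end


# ---------------------------------------------------------------------------
# I/O


@dataclass(frozen=True)
class ColumnMapping:
    """Maps an export dialect onto the canonical registry/encounter schema.

    ``source_vocabulary`` translates local source strings (e.g. "OP", "门诊")
    to the five canonical values; unmapped values must already be canonical.
    ``icd_delimiter`` splits multi-valued ICD cells.
    """

    registry: Mapping[str, str] = field(
        default_factory=lambda: {
            "patient_id": "patient_id",
            "registration_date": "registration_date",
            "death_date": "death_date",
        }
    )
    encounters: Mapping[str, str] = field(
        default_factory=lambda: {
            "patient_id": "patient_id",
            "source": "source",
            "date": "date",
            "diagnosis_text": "diagnosis_text",
            "icd_codes": "icd_codes",
        }
    )
    source_vocabulary: Mapping[str, str] = field(default_factory=dict)
    icd_delimiter: str = ";"


def load_cohort_config(path: "str | Path") -> tuple[StudyWindow, ColumnMapping]:
    """Read a YAML config holding the study window and column mappings."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    try:
        w = cfg["study_window"]
        window = StudyWindow(
            study_start=_parse_date(w["study_start"]),
            study_end=_parse_date(w["study_end"]),
            washout_days=int(w.get("washout_days", 365)),
            admission_link_days=int(w.get("admission_link_days", 30)),
        )
    except KeyError as exc:
        raise ConfigError(f"cohort config missing key: {exc}") from None
    mapping = ColumnMapping(
        registry=cfg.get("registry_columns", ColumnMapping().registry),
        encounters=cfg.get("encounter_columns", ColumnMapping().encounters),
        source_vocabulary=cfg.get("source_vocabulary", {}),
        icd_delimiter=cfg.get("icd_delimiter", ";"),
    )
    return window, mapping


@dataclass
class LoadReport:
    """Accounting for a cohort load: what was read, dropped, and why."""

    registry_rows: int = 0
    encounter_rows: int = 0
    encounters_kept: int = 0
    duplicates_dropped: int = 0
    out_of_window: int = 0
    orphan_encounters: int = 0
    row_errors: list = field(default_factory=list)

    def add_error(self, table: str, row: int, message: str) -> None:
        self.row_errors.append({"table": table, "row": row, "error": message})


def _parse_date(value) -> dt.date:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        raise ValueError("missing date")
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    s = str(value).strip()
    if not s or s.lower() in {"nan", "nat", "none", "na"}:
        raise ValueError("missing date")
    return dt.date.fromisoformat(s)


def _read_table(source, fmt: str | None = None) -> pd.DataFrame:
    """Read CSV/TSV or line-delimited JSON into a DataFrame of strings."""
    if isinstance(source, pd.DataFrame):
        return source.copy()
    path = Path(source)
    suffix = (fmt or path.suffix.lstrip(".")).lower()
    if suffix in {"json", "jsonl", "ndjson"}:
        with open(path, "r", encoding="utf-8") as fh:
            rows = [json.loads(line) for line in fh if line.strip()]
        return pd.DataFrame(rows)
    sep = "\t" if suffix in {"tsv", "tab"} else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _cell(row, col):
    v = row.get(col)
    if v is None or (isinstance(v, float) and pd.isna(v)):
        return ""
    return str(v).strip()


def load_cohort(
    registry_source,
    encounter_source,
    window: StudyWindow,
    mapping: ColumnMapping | None = None,
) -> tuple[list, LoadReport]:
    """Assemble one :class:`PatientRecord` per registry row.

    Accepts paths to CSV/TSV/line-delimited-JSON files or DataFrames.
    Encounters are attached to their patient, deduplicated on exact row
    content, restricted to the study window, and sorted by date.  Rows with
    unparseable dates or unknown sources are collected in the
    :class:`LoadReport` rather than silently dropped.  Patients with zero
    encounters are retained: they are true negatives for every algorithm.
    """
    mapping = mapping or ColumnMapping()
    report = LoadReport()

    reg = _read_table(registry_source)
    enc = _read_table(encounter_source)
    report.registry_rows = len(reg)
    report.encounter_rows = len(enc)
    rcols, ecols = mapping.registry, mapping.encounters

    patients: dict[str, PatientRecord] = {}
    blank_patients: list[PatientRecord] = []
    for i, row in enumerate(reg.to_dict("records")):
        pid = _cell(row, rcols["patient_id"])
        reg_date = None
        raw_reg = _cell(row, rcols.get("registration_date", "registration_date"))
        if raw_reg:
            try:
                reg_date = _parse_date(raw_reg)
            except ValueError:
                report.add_error("registry", i, f"unparseable registration date {raw_reg!r}")
        death = None
        raw_death = _cell(row, rcols.get("death_date", "death_date"))
        if raw_death:
            try:
                death = _parse_date(raw_death)
            except ValueError:
                report.add_error("registry", i, f"unparseable death date {raw_death!r}")
        record = PatientRecord(pid, reg_date, death)
        if pid:
            patients[pid] = record
        else:
            blank_patients.append(record)

    seen_rows: set = set()
    for i, row in enumerate(enc.to_dict("records")):
        pid = _cell(row, ecols["patient_id"])
        raw_source = _cell(row, ecols["source"])
        raw_source = mapping.source_vocabulary.get(raw_source, raw_source)
        try:
            source = Source.coerce(raw_source)
        except DataError as exc:
            report.add_error("encounters", i, str(exc))
            continue
        try:
            date = _parse_date(_cell(row, ecols["date"]))
        except ValueError:
            report.add_error("encounters", i, f"unparseable encounter date")
            continue
        text = _cell(row, ecols.get("diagnosis_text", "diagnosis_text"))
        codes = frozenset(
            c.strip()
            for c in _cell(row, ecols.get("icd_codes", "icd_codes")).split(mapping.icd_delimiter)
            if c.strip()
        )
        key = (pid, source, date, text, codes)
        if key in seen_rows:
            report.duplicates_dropped += 1
            continue
        seen_rows.add(key)
        if not window.contains(date):
            report.out_of_window += 1
            continue
        if pid not in patients:
            report.orphan_encounters += 1
            continue
        try:
            patients[pid].encounters.append(Encounter(pid, source, date, text, codes))
        except DataError as exc:
            report.add_error("encounters", i, str(exc))
            continue
        report.encounters_kept += 1

    records = list(patients.values()) + blank_patients
    for p in records:
        p.encounters.sort(key=lambda e: (e.date, e.source.value))
    return records, report


REASON_MISSING_REGISTRATION = "missing_registration_date"
REASON_MISSING_ID = "missing_patient_id"


def apply_cohort_filters(patients: Iterable[PatientRecord]):
    """Partition patients into (included, excluded-with-reasons).

    A patient is excluded iff the registration date is absent or the patient
    identifier is absent/blank; reason tags are exactly
    ``missing_registration_date`` and ``missing_patient_id``.
    """
    included: list[PatientRecord] = []
    excluded: list[tuple[PatientRecord, tuple[str, ...]]] = []
    for p in patients:
        reasons = []
        if not p.patient_id or not p.patient_id.strip():
            reasons.append(REASON_MISSING_ID)
        if p.registration_date is None:
            reasons.append(REASON_MISSING_REGISTRATION)
        if reasons:
            excluded.append((p, tuple(reasons)))
        else:
            included.append(p)
    return included, excluded


def cohort_to_frames(patients: Sequence[PatientRecord], icd_delimiter: str = ";"):
    """Serialize a cohort back to (registry, encounters) DataFrames.

    Inverse of :func:`load_cohort` on clean data, so loading the written
    frames reproduces the same records.
    """
    reg_rows = [
        {
            "patient_id": p.patient_id,
            "registration_date": p.registration_date.isoformat() if p.registration_date else "",
            "death_date": p.death_date.isoformat() if p.death_date else "",
        }
        for p in patients
    ]
    enc_rows = [
        {
            "patient_id": e.patient_id,
            "source": e.source.value,
            "date": e.date.isoformat(),
            "diagnosis_text": e.diagnosis_text,
            "icd_codes": icd_delimiter.join(sorted(e.icd_codes)),
        }
        for p in patients
        for e in p.encounters
    ]
    reg_cols = ["patient_id", "registration_date", "death_date"]
    enc_cols = ["patient_id", "source", "date", "diagnosis_text", "icd_codes"]
    return (
        pd.DataFrame(reg_rows, columns=reg_cols),
        pd.DataFrame(enc_rows, columns=enc_cols),
    )


def write_cohort(patients: Sequence[PatientRecord], registry_path, encounters_path,
                 icd_delimiter: str = ";") -> None:
    reg, enc = cohort_to_frames(patients, icd_delimiter=icd_delimiter)
    reg.to_csv(registry_path, index=False)
    enc.to_csv(encounters_path, index=False)
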