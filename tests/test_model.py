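"""Cohort loading, deduplication, window filtering, and inclusion filters."""

import datetime as dt
import random

import pandas as pd
import pytest

from phenorule import (
    ColumnMapping,
    DataError,
    Encounter,
    PatientRecord,
    apply_cohort_filters,
    cohort_to_frames,
    load_cohort,
)
from phenorule.model import REASON_MISSING_ID, REASON_MISSING_REGISTRATION

from conftest import enc, patient


def _registry(rows):
    return pd.DataFrame(rows, columns=["patient_id", "registration_date", "death_date"])


def _encounters(rows):
    return pd.DataFrame(
        rows, columns=["patient_id", "source", "date", "diagnosis_text", "icd_codes"]
    )


@pytest.fixture
def small_tables():
    reg = _registry(
        [
            ("a", "2010-01-01", ""),
            ("b", "2011-06-01", ""),
            ("c", "2012-01-01", ""),
        ]
    )
    enc_rows = [
        ("a", "outpatient", "2015-01-01", "rheumatoid arthritis", ""),
        ("a", "discharge", "2015-02-01", "", "M06.9"),
        ("b", "admission", "2016-03-01", "follow-up", "K51.9"),
        ("b", "outpatient", "2016-04-01", "ulcerative colitis", ""),
        ("c", "inpatient", "2017-05-05", "Hashimoto thyroiditis", "E06.3"),
    ]
    return reg, _encounters(enc_rows)


def test_load_partitions_encounters_by_patient(small_tables, window):
    reg, encs = small_tables
    patients, report = load_cohort(reg, encs, window)
    by_id = {p.patient_id: p for p in patients}
    assert set(by_id) == {"a", "b", "c"}
    assert [len(by_id[k].encounters) for k in "abc"] == [2, 2, 1]
    assert report.encounters_kept == 5 and not report.row_errors


def test_out_of_window_encounters_counted_not_kept(small_tables, window):
    reg, encs = small_tables
    encs.loc[len(encs)] = ("a", "outpatient", "2005-01-01", "old visit", "")
    patients, report = load_cohort(reg, encs, window)
    assert report.out_of_window == 1
    assert len(next(p for p in patients if p.patient_id == "a").encounters) == 2


def test_exact_duplicate_rows_deduplicated_with_set_semantics(small_tables, window):
    # oracle: distinct row tuples
    reg, encs = small_tables
    dup = pd.concat([encs, encs.iloc[[0, 0, 3]]], ignore_index=True)
    expected_unique = len({tuple(r) for r in dup.itertuples(index=False)})
    patients, report = load_cohort(reg, dup, window)
    assert report.duplicates_dropped == len(dup) - expected_unique == 3
    assert sum(len(p.encounters) for p in patients) == expected_unique


def test_same_day_distinct_diagnoses_kept(small_tables, window):
    reg, encs = small_tables
    encs.loc[len(encs)] = ("a", "outpatient", "2015-01-01", "different text", "")
    patients, _ = load_cohort(reg, encs, window)
    a = next(p for p in patients if p.patient_id == "a")
    assert len(a.encounters) == 3


def test_row_errors_collected_not_silently_dropped(small_tables, window):
    reg, encs = small_tables
    encs.loc[len(encs)] = ("a", "outpatient", "not-a-date", "x", "")
    encs.loc[len(encs)] = ("a", "telepathy", "2015-06-01", "x", "")
    _, report = load_cohort(reg, encs, window)
    assert len(report.row_errors) == 2
    assert any("telepathy" in e["error"] for e in report.row_errors)


def test_encounter_order_stable_under_shuffled_input(small_tables, window):
    reg, encs = small_tables
    ref, _ = load_cohort(reg, encs, window)
    rng = random.Random(7)
    for _ in range(5):
        shuffled = encs.sample(frac=1, random_state=rng.randint(0, 10**6)).reset_index(drop=True)
        got, _ = load_cohort(reg, shuffled, window)
        assert {p.patient_id: p.encounters for p in got} == {
            p.patient_id: p.encounters for p in ref
        }


def test_roundtrip_through_writer_is_idempotent(small_tables, window, tmp_path):
    reg, encs = small_tables
    patients, _ = load_cohort(reg, encs, window)
    reg2, enc2 = cohort_to_frames(patients)
    reg2.to_csv(tmp_path / "r.csv", index=False)
    enc2.to_csv(tmp_path / "e.csv", index=False)
    reloaded, _ = load_cohort(tmp_path / "r.csv", tmp_path / "e.csv", window)
    assert {p.patient_id: p.encounters for p in reloaded} == {
        p.patient_id: p.encounters for p in patients
    }


def test_column_mapping_and_source_vocabulary(window):
    reg = pd.DataFrame({"pid": ["a"], "reg": ["2010-01-01"], "dod": [""]})
    encs = pd.DataFrame(
        {"pid": ["a"], "src": ["门诊"], "when": ["2015-01-01"], "dx": ["x"], "codes": ["K51|K50"]}
    )
    mapping = ColumnMapping(
        registry={"patient_id": "pid", "registration_date": "reg", "death_date": "dod"},
        encounters={"patient_id": "pid", "source": "src", "date": "when",
                    "diagnosis_text": "dx", "icd_codes": "codes"},
        source_vocabulary={"门诊": "outpatient"},
        icd_delimiter="|",
    )
    patients, report = load_cohort(reg, encs, window, mapping)
    (p,) = patients
    assert p.encounters[0].source.value == "outpatient"
    assert p.encounters[0].icd_codes == {"K51", "K50"}
    assert not report.row_errors


def test_jsonl_reader(tmp_path, window):
    (tmp_path / "r.jsonl").write_text(
        '{"patient_id": "a", "registration_date": "2010-01-01", "death_date": ""}\n'
    )
    (tmp_path / "e.jsonl").write_text(
        '{"patient_id": "a", "source": "outpatient", "date": "2015-01-01", '
        '"diagnosis_text": "ulcerative colitis", "icd_codes": ""}\n'
    )
    patients, _ = load_cohort(tmp_path / "r.jsonl", tmp_path / "e.jsonl", window)
    assert patients[0].encounters[0].diagnosis_text == "ulcerative colitis"


def test_encounter_requires_text_or_codes():
    with pytest.raises(DataError):
        Encounter("a", "outpatient", dt.date(2015, 1, 1), "", frozenset())


def test_death_before_registration_rejected():
    with pytest.raises(DataError):
        PatientRecord("a", dt.date(2015, 1, 1), dt.date(2014, 1, 1))


def test_cohort_filters_partition_and_reasons():
    ok = patient("a")
    no_reg = PatientRecord("b", None)
    no_id = PatientRecord("  ", dt.date(2010, 1, 1))
    neither = PatientRecord("", None)
    included, excluded = apply_cohort_filters([ok, no_reg, no_id, neither])
    assert included == [ok]
    reasons = {id(p): set(r) for p, r in excluded}
    assert reasons[id(no_reg)] == {REASON_MISSING_REGISTRATION}
    assert reasons[id(no_id)] == {REASON_MISSING_ID}
    assert reasons[id(neither)] == {REASON_MISSING_ID, REASON_MISSING_REGISTRATION}
    # partition: nothing lost, nothing in both
    assert len(included) + len(excluded) == 4


def test_cohort_filters_count_conservation():
    patients = [patient(f"p{i}") for i in range(8)] + [PatientRecord(f"q{i}", None) for i in range(2)]
    included, excluded = apply_cohort_filters(patients)
    assert (len(included), len(excluded)) == (8, 2)


def test_zero_encounter_patients_retained(window):
    reg = _registry([("lonely", "2010-01-01", "")])
    patients, _ = load_cohort(reg, _encounters([]), window)
    assert patients[0].patient_id == "lonely" and patients[0].encounters == []
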