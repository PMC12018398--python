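"""Matchers, component multiplicity semantics, composites, and the builtin library."""

import datetime as dt
import random

import pytest
from hypothesis import given, settings, strategies as st

from phenorule import (
    ComponentAlgorithm,
    CompositeAlgorithm,
    ConfigError,
    Matcher,
    builtin_library,
    evaluate_component,
    evaluate_composite,
    match_encounter,
    rules_from_yaml,
    rules_to_yaml,
)

from conftest import day, enc, patient

RA_ICD = Matcher.icd(r"M0[56]\.[389]")
HT_TERM = Matcher.term("Hashimoto", "lymphocytic goiter")


@pytest.mark.parametrize(
    "matcher,encounter,expected",
    [
        (RA_ICD, enc("p", "discharge", 0, "", {"M06.9"}), True),
        (RA_ICD, enc("p", "discharge", 0, "", {"M05.1"}), False),
        (RA_ICD, enc("p", "discharge", 0, "", {"M05.31"}), True),  # subcode of M05.3
        (Matcher.icd("K51"), enc("p", "outpatient", 0, "", {"K51.902"}), True),
        (Matcher.icd("K51"), enc("p", "outpatient", 0, "", {"K519"}), True),  # dotless export
        (Matcher.icd("K51"), enc("p", "outpatient", 0, "", {"K5"}), False),
        (Matcher.icd("K51"), enc("p", "outpatient", 0, "", {"K52.1"}), False),
        (Matcher.icd("D69.3"), enc("p", "outpatient", 0, "", {"D69.4"}), False),
        (HT_TERM, enc("p", "outpatient", 0, "chronic lymphocytic goiter, euthyroid"), True),
        (HT_TERM, enc("p", "outpatient", 0, "HASHIMOTO thyroiditis"), True),  # Latin case-folded
        (HT_TERM, enc("p", "outpatient", 0, "autoimmune thyroiditis"), False),
        # CJK substring, NFKC normalization of the fullwidth numeral
        (Matcher.term("1型糖尿病"), enc("p", "outpatient", 0, "１型糖尿病酮症"), True),
        (Matcher.term("1型糖尿病"), enc("p", "outpatient", 0, "2型糖尿病"), False),
    ],
)
def test_match_encounter(matcher, encounter, expected):
    assert match_encounter(matcher, encounter) is expected


def test_invalid_regex_fails_at_construction_not_match_time():
    with pytest.raises(ConfigError):
        Matcher.icd("M0[56")


def test_empty_term_list_rejected():
    with pytest.raises(ConfigError):
        Matcher.term("", "  ")


def _comp(min_count=1, source="outpatient", conjunct=None, window_days=None):
    return ComponentAlgorithm("c", source, Matcher.term("ulcerative colitis"),
                              conjunct=conjunct, min_count=min_count,
                              window_days=window_days)


def test_min_count_two_needs_two_distinct_dates():
    one = patient("p", enc("p", "outpatient", 0, "ulcerative colitis"))
    sat, _, dates = evaluate_component(_comp(min_count=2), one)
    assert not sat and dates == {day(0)}

    two = patient(
        "p",
        enc("p", "outpatient", 4, "ulcerative colitis"),
        enc("p", "outpatient", 60, "ulcerative colitis again"),
    )
    sat, sat_date, _ = evaluate_component(_comp(min_count=2), two)
    assert sat and sat_date == day(60)  # threshold reached at the 2nd date


def test_same_day_records_count_once():
    p = patient(
        "p",
        enc("p", "outpatient", 0, "ulcerative colitis"),
        enc("p", "outpatient", 0, "ulcerative colitis, recheck"),
    )
    sat, _, dates = evaluate_component(_comp(min_count=2), p)
    assert not sat and dates == {day(0)}


def test_wrong_source_never_matches():
    p = patient("p", enc("p", "discharge", 0, "ulcerative colitis"))
    assert not evaluate_component(_comp(source="outpatient"), p)[0]


def test_conjunct_must_hold_on_same_encounter():
    comp = ComponentAlgorithm(
        "t1d8", "discharge", Matcher.icd("E10"), conjunct=Matcher.term("diabetic ketosis")
    )
    code_only = patient("p", enc("p", "discharge", 0, "diabetes", {"E10.1"}))
    assert not evaluate_component(comp, code_only)[0]
    both_split = patient(
        "p",
        enc("p", "discharge", 0, "diabetes", {"E10.1"}),
        enc("p", "discharge", 1, "diabetic ketosis"),
    )
    assert not evaluate_component(comp, both_split)[0]
    both_same = patient("p", enc("p", "discharge", 0, "diabetic ketosis", {"E10.1"}))
    assert evaluate_component(comp, both_same)[0]


def test_optional_window_days_constraint():
    p = patient(
        "p",
        enc("p", "outpatient", 0, "ulcerative colitis"),
        enc("p", "outpatient", 400, "ulcerative colitis"),
    )
    assert evaluate_component(_comp(min_count=2), p)[0]  # unbounded default
    assert not evaluate_component(_comp(min_count=2, window_days=180), p)[0]


def test_composite_first_flag_is_min_over_components():
    a = ComponentAlgorithm("A", "outpatient", Matcher.term("ulcerative colitis"))
    b = ComponentAlgorithm("B", "discharge", Matcher.icd("K51"))
    algo = CompositeAlgorithm("ibd", (a, b))
    p = patient(
        "p",
        enc("p", "discharge", 31, "", {"K51.9"}),
        enc("p", "outpatient", 120, "ulcerative colitis"),
    )
    res = evaluate_composite(algo, p)
    assert res.flagged and res.first_flag_date == day(31)
    assert res.fired_components == {"A", "B"}

    empty = evaluate_composite(algo, patient("q", enc("q", "outpatient", 0, "gastritis")))
    assert not empty.flagged and empty.first_flag_date is None and not empty.fired_components


@settings(deadline=None, derandomize=True)
@given(st.integers(1, 6), st.lists(st.integers(0, 40), min_size=0, max_size=12))
def test_raising_min_count_is_antitone(min_count, offsets):
    p = patient("p", *[enc("p", "outpatient", o, "ulcerative colitis") for o in set(offsets)])
    sat_hi = evaluate_component(_comp(min_count=min_count + 1), p)[0]
    sat_lo = evaluate_component(_comp(min_count=min_count), p)[0]
    assert not (sat_hi and not sat_lo)


@settings(deadline=None, derandomize=True)
@given(st.randoms(use_true_random=False))
def test_composite_invariant_to_encounter_order(rnd):
    encs = [
        enc("p", src, off, text, codes)
        for src, off, text, codes in [
            ("outpatient", 3, "ulcerative colitis", ()),
            ("discharge", 9, "", ("K51.1",)),
            ("outpatient", 40, "gastritis", ()),
            ("admission", 80, "Crohn disease", ()),
        ]
    ]
    rnd.shuffle(encs)
    comps, final = builtin_library(language="en")["ibd"]
    res = evaluate_composite(final, patient("p", *encs))
    # outpatient UC needs 3 dates (IBD-11) and discharge K51 (IBD-8) is not in
    # the final composite, so only the admission Crohn record fires
    assert res.flagged and res.first_flag_date == day(80)
    assert res.fired_components == {"IBD-1"}


def test_monotone_under_adding_components():
    comps, final = builtin_library(language="en")["ibd"]
    p = patient("p", enc("p", "discharge", 10, "Crohn disease of ileum"))
    small = CompositeAlgorithm("ibd", (comps[4],))  # discharge Crohn term
    assert evaluate_composite(small, p).flagged
    assert evaluate_composite(final, p).flagged  # superset composite still flags


# -- builtin library ---------------------------------------------------------


def test_library_shape_and_final_memberships():
    lib = builtin_library()
    nums = lambda alg: [int(c.id.split("-")[1]) for c in alg.components]
    assert set(lib) == {"hashimoto", "ibd", "itp", "ra", "t1d"}
    assert nums(lib["hashimoto"][1]) == [1, 2, 3, 4, 5, 6]
    assert nums(lib["ibd"][1]) == [1, 3, 5, 6, 9, 10, 11, 12]
    assert nums(lib["itp"][1]) == [1, 2, 3, 5, 9, 10, 11, 12]
    assert nums(lib["ra"][1]) == [1, 2, 3, 4, 5, 6]
    assert nums(lib["t1d"][1]) == [1, 2, 5, 10, 11, 12]
    assert all(len(lib[d][0]) == 12 for d in ("ibd", "itp", "t1d"))


def test_library_thresholds_and_compounds():
    lib = builtin_library()
    by_id = {c.id: c for d in lib for c in lib[d][0]}
    assert by_id["IBD-11"].min_count == 3 and by_id["IBD-12"].min_count == 3
    assert by_id["ITP-10"].min_count == 2 and by_id["ITP-11"].min_count == 2
    assert by_id["T1D-9"].min_count == 2 and by_id["T1D-10"].min_count == 2
    assert by_id["T1D-4"].conjunct is not None and by_id["T1D-8"].conjunct is not None
    assert by_id["T1D-12"].matcher.kind == "any" and by_id["T1D-12"].conjunct is not None
    assert by_id["RA-2"].matcher.pattern == r"M0[56]\.[389]"
    assert "lymphocytic goiter" in by_id["HASHIMOTO-1"].matcher.terms


def test_t1d_outpatient_compound_matches_term_or_code_with_ketosis():
    comp = {c.id: c for c in builtin_library(language="en")["t1d"][0]}["T1D-12"]
    term_route = patient("p", enc("p", "outpatient", 0, "type 1 diabetes diabetic ketosis"))
    code_route = patient("p", enc("p", "outpatient", 0, "diabetic ketosis", {"E10.1"}))
    neither = patient("p", enc("p", "outpatient", 0, "diabetic ketosis"))
    assert evaluate_component(comp, term_route)[0]
    assert evaluate_component(comp, code_route)[0]
    assert not evaluate_component(comp, neither)[0]


def test_rule_yaml_roundtrip(tmp_path):
    lib = builtin_library()
    text = rules_to_yaml(lib, tmp_path / "rules.yaml")
    back = rules_from_yaml(tmp_path / "rules.yaml")
    assert set(back) == set(lib)
    for disease in lib:
        assert back[disease][0] == lib[disease][0]
        assert back[disease][1] == lib[disease][1]
    assert rules_to_yaml(back) == text
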