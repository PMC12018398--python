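"""The phenotype rule DSL and its evaluator.

A phenotype is expressed as an OR-composite of *component algorithms*; each
component fixes a record source, a matcher (free-text synonym list, ICD-10
code pattern, or a disjunction of both), an optional conjunct matcher that
must co-occur on the same encounter, and a multiplicity threshold counted in
distinct calendar dates.

Text matching is substring containment on NFKC-normalized, case-folded text
(Unicode-exact for CJK).  ICD matching supports bare code prefixes ("K51"
matches "K51.902" and dotless "K519") and start-anchored regular expressions
(e.g. ``M0[56]\\.[389]``), compiled once at rule-construction time.
"""

from __future__ import annotations

import datetime as dt
import re
import unicodedata
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .errors import ConfigError
from .model import Encounter, PatientRecord, Source

__all__ = [
    "Matcher",
    "ComponentAlgorithm",
    "CompositeAlgorithm",
    "FlagResult",
    "match_encounter",
    "evaluate_component",
    "evaluate_composite",
    "rules_to_yaml",
    "rules_from_yaml",
]

_REGEX_CHARS = set("[](){}|?*+\\^$")


def _normalize_text(text: str) -> str:
    return unicodedata.normalize("NFKC", text).casefold()


@dataclass(frozen=True)
class Matcher:
    """A single matching condition against one encounter.

    kind="term": ``terms`` is a synonym list; match iff any synonym occurs as
    a contiguous substring of the normalized diagnosis text.
    kind="icd": ``pattern`` is a bare ICD-10 prefix or a regex; match iff any
    code on the encounter matches.
    kind="any": disjunction over ``alternatives`` (used for compound rules
    whose primary condition is "term or code").
    """

    kind: str
    pattern: str = ""
    terms: tuple = ()
    alternatives: tuple = ()

    def __post_init__(self):
        if self.kind not in {"term", "icd", "any"}:
            raise ConfigError(f"unknown matcher kind {self.kind!r}")
        if self.kind == "term":
            terms = tuple(t for t in self.terms if t and t.strip())
            if not terms:
                raise ConfigError("term matcher needs at least one non-empty synonym")
            object.__setattr__(self, "terms", terms)
            object.__setattr__(
                self, "_norm_terms", tuple(_normalize_text(t) for t in terms)
            )
        elif self.kind == "icd":
            if not self.pattern or not self.pattern.strip():
                raise ConfigError("icd matcher needs a non-empty pattern")
            pattern = self.pattern.strip()
            object.__setattr__(self, "pattern", pattern)
            if _REGEX_CHARS & set(pattern):
                try:
                    rx = re.compile(pattern, re.IGNORECASE)
                except re.error as exc:
                    raise ConfigError(f"invalid ICD regex {pattern!r}: {exc}") from None
                object.__setattr__(self, "_regex", rx)
            else:
                object.__setattr__(self, "_regex", None)
        else:
            if not self.alternatives:
                raise ConfigError("'any' matcher needs at least one alternative")
            object.__setattr__(self, "alternatives", tuple(self.alternatives))

    # -- constructors ------------------------------------------------------
    @staticmethod
    def term(*synonyms: str) -> "Matcher":
        return Matcher(kind="term", terms=tuple(synonyms))

    @staticmethod
    def icd(pattern: str) -> "Matcher":
        return Matcher(kind="icd", pattern=pattern)

    @staticmethod
    def any_of(*alternatives: "Matcher") -> "Matcher":
        return Matcher(kind="any", alternatives=tuple(alternatives))

    # -- matching ----------------------------------------------------------
    def _match_code(self, code: str) -> bool:
        code = code.strip().upper()
        rx = getattr(self, "_regex", None)
        if rx is not None:
            return rx.match(code) is not None
        prefix = self.pattern.upper()
        if code == prefix:
            return True
        if code.startswith(prefix):
            nxt = code[len(prefix)]
            # boundary: a dot, or a digit (dotless exports like "K519")
            return nxt == "." or nxt.isdigit()
        return False

    def matches(self, encounter: Encounter) -> bool:
        if self.kind == "term":
            text = _normalize_text(encounter.diagnosis_text)
            return any(t in text for t in self._norm_terms)
        if self.kind == "icd":
            return any(self._match_code(c) for c in encounter.icd_codes)
        return any(alt.matches(encounter) for alt in self.alternatives)


def match_encounter(matcher: Matcher, encounter: Encounter) -> bool:
    """Does a single encounter satisfy the matcher?"""
    return matcher.matches(encounter)


@dataclass(frozen=True)
class ComponentAlgorithm:
    """One source x matcher x multiplicity condition.

    ``conjunct``, when present, must hold on the same encounter as
    ``matcher`` (record-level AND).  ``min_count`` counts distinct calendar
    dates of qualifying encounters; ``window_days`` optionally requires those
    dates to fall within a sliding window (default: unbounded).
    """

    id: str
    source: Source
    matcher: Matcher
    conjunct: Matcher | None = None
    min_count: int = 1
    window_days: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "source", Source.coerce(self.source))
        if self.min_count < 1:
            raise ConfigError(f"component {self.id!r}: min_count must be >= 1")
        if self.window_days is not None and self.window_days < 1:
            raise ConfigError(f"component {self.id!r}: window_days must be >= 1")

    def matches_encounter(self, encounter: Encounter, ignore_source: bool = False) -> bool:
        if not ignore_source and encounter.source != self.source:
            return False
        if not self.matcher.matches(encounter):
            return False
        return self.conjunct is None or self.conjunct.matches(encounter)


def evaluate_component(component: ComponentAlgorithm, patient: PatientRecord):
    """Evaluate one component against a patient.

    Returns ``(satisfied, satisfaction_date, matching_dates)``:
    ``matching_dates`` are the distinct dates of qualifying encounters of the
    component's source; the component is satisfied once ``min_count`` of them
    exist (within ``window_days``, if set), and the satisfaction date is the
    date on which the threshold is first reached.
    """
    dates = sorted({e.date for e in patient.encounters if component.matches_encounter(e)})
    m = component.min_count
    if len(dates) < m:
        return False, None, set(dates)
    if component.window_days is None:
        return True, dates[m - 1], set(dates)
    for k in range(m - 1, len(dates)):
        if (dates[k] - dates[k - m + 1]).days <= component.window_days:
            return True, dates[k], set(dates)
    return False, None, set(dates)


@dataclass(frozen=True)
class CompositeAlgorithm:
    """An OR-composite of components for one disease."""

    disease: str
    components: tuple

    def __post_init__(self):
        comps = tuple(self.components)
        if not comps:
            raise ConfigError(f"composite for {self.disease!r} has no components")
        ids = [c.id for c in comps]
        if len(set(ids)) != len(ids):
            raise ConfigError(f"composite for {self.disease!r} has duplicate component ids")
        object.__setattr__(self, "components", comps)

    def component_ids(self) -> tuple:
        return tuple(c.id for c in self.components)

    def subset(self, ids: Iterable[str]) -> "CompositeAlgorithm":
        wanted = set(ids)
        missing = wanted - set(self.component_ids())
        if missing:
            raise ConfigError(f"unknown component ids: {sorted(missing)}")
        return CompositeAlgorithm(
            self.disease, tuple(c for c in self.components if c.id in wanted)
        )


@dataclass(frozen=True)
class FlagResult:
    patient_id: str
    flagged: bool
    first_flag_date: dt.date | None
    fired_components: frozenset

    def __post_init__(self):
        object.__setattr__(self, "fired_components", frozenset(self.fired_components))


def evaluate_composite(algorithm: CompositeAlgorithm, patient: PatientRecord) -> FlagResult:
    """Evaluate the OR-composite: flagged iff any component is satisfied.

    ``first_flag_date`` is the earliest satisfaction date over fired
    components; when two components fire on the same date both are listed.
    """
    fired = {}
    for comp in algorithm.components:
        satisfied, sat_date, _ = evaluate_component(comp, patient)
        if satisfied:
            fired[comp.id] = sat_date
    if not fired:
        return FlagResult(patient.patient_id, False, None, frozenset())
    return FlagResult(patient.patient_id, True, min(fired.values()), frozenset(fired))


# ---------------------------------------------------------------------------
# YAML serialization of rule libraries


def _matcher_to_dict(m: Matcher) -> dict:
    if m.kind == "term":
        return {"kind": "term", "terms": list(m.terms)}
    if m.kind == "icd":
        return {"kind": "icd", "pattern": m.pattern}
    return {"kind": "any", "alternatives": [_matcher_to_dict(a) for a in m.alternatives]}


def _matcher_from_dict(d: Mapping) -> Matcher:
    kind = d.get("kind")
    if kind == "term":
        return Matcher.term(*d["terms"])
    if kind == "icd":
        return Matcher.icd(d["pattern"])
    if kind == "any":
        return Matcher.any_of(*(_matcher_from_dict(a) for a in d["alternatives"]))
    raise ConfigError(f"unknown matcher kind in rules file: {kind!r}")


def rules_to_yaml(library: Mapping[str, tuple], path=None) -> str:
    """Serialize ``{disease: (components, final_composite)}`` to YAML.

    Round-trips losslessly through :func:`rules_from_yaml`.
    """
    doc = {}
    for disease, (components, final) in library.items():
        doc[disease] = {
            "components": [
                {
                    "id": c.id,
                    "source": c.source.value,
                    "matcher": _matcher_to_dict(c.matcher),
                    **({"conjunct": _matcher_to_dict(c.conjunct)} if c.conjunct else {}),
                    **({"min_count": c.min_count} if c.min_count != 1 else {}),
                    **({"window_days": c.window_days} if c.window_days else {}),
                }
                for c in components
            ],
            "final": list(final.component_ids()),
        }
    text = yaml.safe_dump(doc, allow_unicode=True, sort_keys=True)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def rules_from_yaml(source) -> dict:
    """Inverse of :func:`rules_to_yaml`."""
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = str(source)
    doc = yaml.safe_load(text)
    library = {}
    for disease, entry in doc.items():
        components = [
            ComponentAlgorithm(
                id=c["id"],
                source=Source.coerce(c["source"]),
                matcher=_matcher_from_dict(c["matcher"]),
                conjunct=_matcher_from_dict(c["conjunct"]) if "conjunct" in c else None,
                min_count=int(c.get("min_count", 1)),
                window_days=c.get("window_days"),
            )
            for c in entry["components"]
        ]
        by_id = {c.id: c for c in components}
        final = CompositeAlgorithm(
            disease, tuple(by_id[i] for i in entry["final"])
        )
        library[disease] = (components, final)
    return library
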