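"""Gold-standard handling: reviewer verdicts and consensus.

Two clinicians independently review each candidate case and return "yes",
"no", or "undeterminable", also flagging previous (prevalent) cases.  On
disagreement a third clinician arbitrates.  The *true-case set* is the set
of patients adjudicated "yes", by default excluding previous cases (only
incident cases are validated).
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .errors import DataError, UnresolvedCaseError

__all__ = [
    "Verdict",
    "ReviewerVerdict",
    "AdjudicatedCase",
    "consensus",
    "consensus_all",
    "true_case_set",
    "read_verdicts",
    "adjudicated_to_frame",
]


class Verdict(str, enum.Enum):
    YES = "yes"
    NO = "no"
    UNDETERMINABLE = "undeterminable"


@dataclass(frozen=True)
class ReviewerVerdict:
    patient_id: str
    reviewer_id: str
    verdict: Verdict
    previous_case: bool = False

    def __post_init__(self):
        object.__setattr__(self, "verdict", Verdict(self.verdict))


@dataclass(frozen=True)
class AdjudicatedCase:
    patient_id: str
    final_verdict: Verdict
    previous_case: bool
    arbitration_used: bool


def consensus(verdicts: Iterable[ReviewerVerdict]) -> AdjudicatedCase:
    """Combine one patient's reviewer verdicts into a final adjudication.

    The first two verdicts are the primary reviewers (the rule is symmetric
    in them); if they agree, that is the final verdict; if they disagree the
    third verdict arbitrates — any disagreement, including one involving
    "undeterminable", goes to arbitration.  The previous-case flag is the OR
    over all reviewers (conservative exclusion of prevalent cases).

    Raises :class:`UnresolvedCaseError` when the primaries disagree and no
    third verdict exists, and :class:`DataError` on fewer than two verdicts
    or mixed patient ids.
    """
    vs = list(verdicts)
    if len(vs) < 2:
        pid = vs[0].patient_id if vs else "<unknown>"
        raise DataError(f"patient {pid!r}: consensus needs at least two reviewer verdicts")
    pids = {v.patient_id for v in vs}
    if len(pids) != 1:
        raise DataError(f"consensus received verdicts for multiple patients: {sorted(pids)}")
    pid = vs[0].patient_id
    previous = any(v.previous_case for v in vs)
    first, second = vs[0].verdict, vs[1].verdict
    if first == second:
        return AdjudicatedCase(pid, first, previous, arbitration_used=False)
    if len(vs) < 3:
        raise UnresolvedCaseError(pid)
    return AdjudicatedCase(pid, vs[2].verdict, previous, arbitration_used=True)


def consensus_all(verdicts: Iterable[ReviewerVerdict]) -> list[AdjudicatedCase]:
    """Group verdicts by patient (input order preserved) and adjudicate each."""
    by_patient: dict[str, list[ReviewerVerdict]] = defaultdict(list)
    for v in verdicts:
        by_patient[v.patient_id].append(v)
    return [consensus(vs) for vs in by_patient.values()]


def true_case_set(cases: Iterable[AdjudicatedCase], include_previous: bool = False) -> set:
    """Patient ids adjudicated "yes"; previous cases excluded by default."""
    return {
        c.patient_id
        for c in cases
        if c.final_verdict == Verdict.YES and (include_previous or not c.previous_case)
    }


# ---------------------------------------------------------------------------
# I/O


def read_verdicts(path) -> list[ReviewerVerdict]:
    """Read a reviewer-verdict CSV: patient_id, reviewer_id, verdict, previous_case."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        ReviewerVerdict(
            patient_id=row["patient_id"],
            reviewer_id=row["reviewer_id"],
            verdict=Verdict(row["verdict"].strip().lower()),
            previous_case=str(row.get("previous_case", "")).strip().lower()
            in {"1", "true", "yes"},
        )
        for _, row in df.iterrows()
    ]


def adjudicated_to_frame(cases: Iterable[AdjudicatedCase]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": c.patient_id,
                "final_verdict": c.final_verdict.value,
                "previous_case": c.previous_case,
                "arbitration_used": c.arbitration_used,
            }
            for c in cases
        ],
        columns=["patient_id", "final_verdict", "previous_case", "arbitration_used"],
    )
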