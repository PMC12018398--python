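"""Algorithm construction: subset search under a PPV floor.

The final composite for a disease is chosen by evaluating every non-empty
subset of its component algorithms (flag set = union of component flag sets)
and keeping the subset with the highest sensitivity among those whose PPV
meets the floor (default 70%).  Ties break toward higher PPV, then fewer
components, then lexicographically smaller id tuples.  Exhaustive
enumeration (components capped at 20, practically <= 12, i.e. <= 4095
subsets) makes the selection rule exact rather than heuristic.

An alternative mode keeps every component whose *individual* PPV meets the
floor and unions them, mirroring a per-component screening procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

from .errors import ConfigError, DataError
from .evaluation import PerformanceEstimate

__all__ = [
    "SelectionConfig",
    "SubsetEstimate",
    "SelectionResult",
    "select_algorithm",
    "pareto_frontier",
]


@dataclass(frozen=True)
class SelectionConfig:
    ppv_floor_pct: float = 70.0
    max_components: int | None = None
    mode: str = "subset_search"  # or "per_component_filter"

    def __post_init__(self):
        if not 0 < self.ppv_floor_pct <= 100:
            raise ConfigError("ppv_floor_pct must lie in (0, 100]")
        if self.mode not in {"subset_search", "per_component_filter"}:
            raise ConfigError(f"unknown selection mode {self.mode!r}")


@dataclass(frozen=True)
class SubsetEstimate:
    """Raw (unrounded) performance of one component subset."""

    ids: tuple
    confirmed: int
    valid: int
    true_cases: int

    @property
    def sensitivity(self) -> float:
        return self.confirmed / self.true_cases if self.true_cases else float("nan")

    @property
    def ppv(self) -> float:
        return self.confirmed / self.valid if self.valid else float("nan")

    def meets_floor(self, floor_pct: float) -> bool:
        # exact integer comparison: 100*confirmed/valid >= floor
        return self.valid > 0 and 100.0 * self.confirmed >= floor_pct * self.valid


@dataclass
class SelectionResult:
    chosen: tuple
    estimate: PerformanceEstimate | None
    frontier: list
    feasible: bool = True
    diagnostics: dict = field(default_factory=dict)


def _sort_key(s: SubsetEstimate):
    # maximize sensitivity, then PPV, then parsimony, then lexicographic ids
    return (-s.sensitivity, -s.ppv, len(s.ids), s.ids)


def select_algorithm(
    component_ids: Sequence[str],
    per_component_flags: Mapping[str, set],
    truth: set,
    cfg: SelectionConfig | None = None,
) -> SelectionResult:
    """Choose the component subset maximizing sensitivity under the PPV floor.

    ``per_component_flags`` maps each component id to its flagged-patient
    set.  Returns the chosen ids, their performance estimate, and the
    sensitivity-PPV Pareto frontier over all enumerated subsets.  When no
    subset meets the floor the result is empty with ``feasible=False``.
    """
    cfg = cfg or SelectionConfig()
    ids = list(component_ids)
    missing = [i for i in ids if i not in per_component_flags]
    if missing:
        raise DataError(f"component ids missing from flag map: {missing}")
    if len(ids) > 20:
        raise ConfigError("exhaustive subset search is capped at 20 components")
    truth = set(truth)
    n_true = len(truth)
    flag_sets = {i: set(per_component_flags[i]) for i in ids}

    if cfg.mode == "per_component_filter":
        kept = []
        for i in sorted(ids):
            f = flag_sets[i]
            single = SubsetEstimate((i,), len(f & truth), len(f), n_true)
            if single.meets_floor(cfg.ppv_floor_pct):
                kept.append(i)
        subsets = [tuple(sorted(kept))] if kept else []
        estimates = [_estimate_subset(s, flag_sets, truth) for s in subsets]
        chosen = estimates[0] if estimates else None
        frontier = pareto_frontier(estimates)
        return _result(chosen, frontier, cfg)

    max_k = min(len(ids), cfg.max_components or len(ids))
    estimates = []
    for k in range(1, max_k + 1):
        for combo in combinations(sorted(ids), k):
            estimates.append(_estimate_subset(combo, flag_sets, truth))
    frontier = pareto_frontier(estimates)
    feasible = [s for s in estimates if s.meets_floor(cfg.ppv_floor_pct)]
    chosen = min(feasible, key=_sort_key) if feasible else None
    return _result(chosen, frontier, cfg)


def _estimate_subset(ids: tuple, flag_sets: Mapping[str, set], truth: set) -> SubsetEstimate:
    union: set = set()
    for i in ids:
        union |= flag_sets[i]
    return SubsetEstimate(tuple(ids), len(union & truth), len(union), len(truth))


def _result(chosen: SubsetEstimate | None, frontier: list, cfg: SelectionConfig) -> SelectionResult:
    if chosen is None:
        return SelectionResult(
            chosen=(),
            estimate=None,
            frontier=frontier,
            feasible=False,
            diagnostics={"reason": f"no subset reaches PPV >= {cfg.ppv_floor_pct}%"},
        )
    return SelectionResult(
        chosen=chosen.ids,
        estimate=PerformanceEstimate.from_counts(
            "+".join(chosen.ids), chosen.confirmed, chosen.valid, chosen.true_cases
        ),
        frontier=frontier,
        feasible=True,
    )


def pareto_frontier(estimates: Sequence[SubsetEstimate]) -> list:
    """Subsets not dominated in (sensitivity, PPV), sorted by sensitivity
    descending.  A dominates B iff A is >= on both axes and > on one;
    coincident points are both kept."""
    ordered = sorted(estimates, key=lambda s: (-s.sensitivity, -s.ppv, len(s.ids), s.ids))
    frontier: list[SubsetEstimate] = []
    best_ppv = float("-inf")
    last_kept: tuple | None = None
    for s in ordered:
        point = (s.sensitivity, s.ppv)
        if s.ppv > best_ppv or point == last_kept:
            frontier.append(s)
            best_ppv = max(best_ppv, s.ppv)
            last_kept = point
    return frontier
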