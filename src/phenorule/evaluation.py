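"""Validation metrics against the chart-review gold standard.

For each algorithm: *valid cases* are the patients it flags within the
adjudicated pool, *confirmed cases* those also adjudicated "yes", and *true
cases* the gold-standard positives.  Sensitivity = confirmed/true x 100%,
PPV = confirmed/valid x 100%, each with a binomial confidence interval.

The default interval is the normal-approximation (Wald) interval
p +/- z*sqrt(p(1-p)/n), truncated to [0, 100] on the percentage scale —
the method whose printed values this table format carries; Wilson and
Clopper-Pearson are available as alternatives (via statsmodels).  Rounding
is half-up to two decimals and happens at render time only; a metric whose
denominator is zero is undefined and rendered "NA".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import norm

from .errors import DataError

__all__ = [
    "PerformanceEstimate",
    "confusion_counts",
    "proportion_pct",
    "wald_ci_pct",
    "binomial_ci_pct",
    "performance_table",
    "performance_frame",
]


def round2(value: float) -> float:
    """Round half-up to 2 decimals (render-time rounding rule)."""
    return float(Decimal(repr(float(value))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def confusion_counts(flagged: set, truth: set, universe: set):
    """(confirmed, valid, true_cases) for one algorithm.

    ``valid`` = |flagged|, ``true_cases`` = |truth|, ``confirmed`` =
    |flagged ∩ truth|.  Both sets must lie inside the evaluation universe.
    """
    stray = set(flagged) - set(universe)
    if stray:
        raise DataError(f"flagged ids outside the evaluation universe: {sorted(stray)[:10]}")
    stray = set(truth) - set(universe)
    if stray:
        raise DataError(f"truth ids outside the evaluation universe: {sorted(stray)[:10]}")
    return len(set(flagged) & set(truth)), len(set(flagged)), len(set(truth))


def proportion_pct(numerator: int, denominator: int):
    """100*numerator/denominator rounded half-up to 2 decimals; None if the
    denominator is zero (rendered "NA")."""
    if numerator < 0 or denominator < 0:
        raise DataError("counts must be non-negative")
    if numerator > denominator:
        raise DataError(f"numerator {numerator} exceeds denominator {denominator}")
    if denominator == 0:
        return None
    return round2(100.0 * numerator / denominator)


def wald_ci_pct(successes: int, trials: int, level: float = 0.95):
    """Truncated Wald binomial CI on the percentage scale.

    p̂ ± z·sqrt(p̂(1−p̂)/n), bounds clipped to [0, 100] and rounded half-up
    to 2 decimals; (lower, upper) or None when trials == 0.  The interval
    has zero width at p̂ ∈ {0, 1}.
    """
    if trials == 0:
        return None
    if not 0 <= successes <= trials:
        raise DataError(f"successes {successes} outside [0, {trials}]")
    z = norm.ppf(0.5 + level / 2.0)
    p = successes / trials
    half = z * math.sqrt(p * (1.0 - p) / trials)
    lower = max(0.0, 100.0 * (p - half))
    upper = min(100.0, 100.0 * (p + half))
    return round2(lower), round2(upper)


def binomial_ci_pct(successes: int, trials: int, level: float = 0.95,
                    method: str = "wald"):
    """Binomial CI on the percentage scale by method: 'wald' (default,
    in-package), 'wilson' or 'clopper-pearson' (statsmodels)."""
    if method == "wald":
        return wald_ci_pct(successes, trials, level)
    if trials == 0:
        return None
    from statsmodels.stats.proportion import proportion_confint

    sm_method = {"wilson": "wilson", "clopper-pearson": "beta"}.get(method)
    if sm_method is None:
        raise DataError(f"unknown CI method {method!r}")
    lo, hi = proportion_confint(successes, trials, alpha=1 - level, method=sm_method)
    return round2(100.0 * lo), round2(100.0 * hi)


@dataclass(frozen=True)
class PerformanceEstimate:
    """One performance-table row: counts plus sensitivity/PPV with CIs.

    Percentages are rounded to 2 decimals; a metric is None ("NA") iff its
    denominator is zero.
    """

    algorithm_id: str
    valid_cases: int
    confirmed_cases: int
    true_cases: int
    sensitivity_pct: float | None
    sensitivity_ci: tuple | None
    ppv_pct: float | None
    ppv_ci: tuple | None

    def __post_init__(self):
        if self.confirmed_cases > self.valid_cases or self.confirmed_cases > self.true_cases:
            raise DataError(
                f"{self.algorithm_id}: confirmed ({self.confirmed_cases}) exceeds "
                f"valid ({self.valid_cases}) or true ({self.true_cases})"
            )

    @staticmethod
    def from_counts(algorithm_id: str, confirmed: int, valid: int, true_cases: int,
                    level: float = 0.95, ci_method: str = "wald") -> "PerformanceEstimate":
        return PerformanceEstimate(
            algorithm_id=algorithm_id,
            valid_cases=valid,
            confirmed_cases=confirmed,
            true_cases=true_cases,
            sensitivity_pct=proportion_pct(confirmed, true_cases),
            sensitivity_ci=binomial_ci_pct(confirmed, true_cases, level, ci_method),
            ppv_pct=proportion_pct(confirmed, valid),
            ppv_ci=binomial_ci_pct(confirmed, valid, level, ci_method),
        )


def performance_table(
    flags: Mapping[str, set],
    truth: set,
    universe: set,
    level: float = 0.95,
    ci_method: str = "wald",
) -> list[PerformanceEstimate]:
    """One :class:`PerformanceEstimate` per algorithm id in ``flags``."""
    rows = []
    for algo_id, flagged in flags.items():
        confirmed, valid, true_cases = confusion_counts(set(flagged), truth, universe)
        rows.append(
            PerformanceEstimate.from_counts(algo_id, confirmed, valid, true_cases,
                                            level=level, ci_method=ci_method)
        )
    return rows


def performance_frame(estimates: Iterable[PerformanceEstimate]) -> pd.DataFrame:
    """Render estimates to a DataFrame; undefined metrics become "NA"."""

    def fmt(value):
        return "NA" if value is None else value

    rows = []
    for e in estimates:
        sen_lo, sen_hi = e.sensitivity_ci or (None, None)
        ppv_lo, ppv_hi = e.ppv_ci or (None, None)
        rows.append(
            {
                "algorithm_id": e.algorithm_id,
                "valid": e.valid_cases,
                "confirmed": e.confirmed_cases,
                "true": e.true_cases,
                "sen_pct": fmt(e.sensitivity_pct),
                "sen_lo": fmt(sen_lo),
                "sen_hi": fmt(sen_hi),
                "ppv_pct": fmt(e.ppv_pct),
                "ppv_lo": fmt(ppv_lo),
                "ppv_hi": fmt(ppv_hi),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["algorithm_id", "valid", "confirmed", "true", "sen_pct", "sen_lo",
                 "sen_hi", "ppv_pct", "ppv_lo", "ppv_hi"],
    )
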