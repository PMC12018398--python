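# Methods

## Scope and data model

The package operates on three tables: a resident registry (one row per
patient: identifier, health-record registration date, optional death date),
an encounter stream (one row per diagnosis record: patient, source, date,
free-text diagnosis, zero or more ICD-10 codes), and reviewer verdicts from
chart review.  Dates are calendar days; nothing in the pipeline uses
times.  Encounters are restricted to the study window at load time, exact
duplicate rows are dropped (EHR exports commonly repeat rows) while
distinct same-day diagnoses are kept, and every load produces an accounting
report (rows read, dropped, per-row parse errors) rather than silent
drops.  Patients with a registry row but no encounters stay in the cohort:
they are true negatives for every algorithm, and denominators must reflect
the registry, not the encounter file.  Cohort exclusions are exactly the
two the validated design used: missing registration date and missing/blank
patient identifier.  Death dates are carried but only truncate
observation; no mortality modelling is attempted.

## Matching semantics

Term matchers hold a synonym list and match when any synonym occurs as a
contiguous substring of the diagnosis text after NFKC normalization and
case folding — Unicode-exact for CJK, case-insensitive for Latin.  The
shipped library carries both Chinese and English synonyms per concept,
selectable per call (`language="zh" | "en" | "both"`, default both, since
source records mix scripts).  There is no negation detection and no Chinese
word segmentation; substring matching can over-trigger on embedded
negatives ("排除类风湿关节炎") and on unlucky substrings (the normalized
type-1 synonym "I型糖尿病" occurs inside "II型糖尿病"; the synthetic
generator uses Arabic numerals for its type-2 distractors for exactly this
reason).  This is a known property of the rule family, not a defect the
engine tries to fix.

ICD matchers accept a bare code prefix or a regular expression.  A prefix P
matches code C iff C == P, or C extends P at a dot or digit boundary —
"K51" matches "K51.9", "K51.902" and the dotless export form "K519", but
not "K52.1".  Regexes are compiled once at rule construction (an invalid
pattern is a configuration error, never a match-time error) and are
anchored at the start of the code, so `M0[56]\.[389]` accepts "M06.9" and
the subcode "M05.31" and rejects "M05.1".  Codes are compared
case-insensitively after whitespace trimming.

A component algorithm fixes a source, a matcher, an optional conjunct (both
matchers must hold on the same record — a record-level AND, used by the
type-1-diabetes compound rules), and a multiplicity threshold counted in
*distinct calendar dates*, not raw rows, with no time-window constraint by
default (a sliding `window_days` knob exists but the shipped library leaves
it unbounded).  One compound rule needs a disjunctive primary ("type-1 term
or E10, together with the ketosis term"), so matchers support an `any`
kind over alternatives.  The satisfaction date is the date the threshold is
first reached (the m-th smallest matching date); composites OR their
components and flag from the earliest satisfaction date, recording every
fired component on ties.  Multiplicity thresholds apply inside final
composites exactly as in the numbered component definitions.

The engine supports emergency and inpatient records as sources, but no
shipped component references them.

## Incident-case classification

Validation is restricted to incident, hospitalized cases.  The package uses
these semantics:

* **Index date** — the date the composite algorithm's conditions are first
  met (multiplicity-aware).  For patients the composite never flags, the
  first evidence date is used.
* **Disease evidence** — any encounter, from any source, matching any
  component's matcher (with its conjunct) at threshold one.  A single prior
  outpatient code is disqualifying history even when no component it
  belongs to is satisfied: washout concerns evidence of prior disease, not
  algorithm satisfaction.
* **Washout** — any evidence record in the `washout_days` (default 365)
  before the index date marks the patient prevalent
  (`prior_history_in_washout`).  The interval is closed at the far end: a
  record exactly 365 days before index disqualifies; 366 days does not.
  Because evidence is scanned at threshold one while the index respects
  thresholds, the first of two visits required by a min-count-2 rule can
  itself violate washout.  A corollary worth knowing: evidence falling
  between the first evidence date and a later index (e.g. a record from a
  source no satisfied component uses) also reads as prior history.
  Patients registered fewer than `washout_days` before index are treated
  as washout-satisfying when their observed span is clean; the
  `strict_washout` switch instead demands a full year of observation
  (favoring specificity over inclusion).
* **Hospitalization** — admission-type sources are admission, inpatient,
  and discharge (a discharge record documents a completed admission).  A
  patient is incident if an admission-type record is among the earliest
  evidence encounters (`admitted_at_initial_diagnosis`), or if the first
  evidence is ambulatory and a disease-matching admission-type record
  follows within `admission_link_days` (default 30; days 1–30 inclusive,
  so day 30 links and day 31 does not).  "One month" is fixed at 30 days to
  keep the rule deterministic.  The `any_admission` switch drops the
  requirement that the linked admission itself carry disease evidence.
  Everyone else is `not_hospitalized` and excluded.

## Adjudication

Two primary reviewers give yes/no/undeterminable verdicts and flag previous
(prevalent) cases; agreement is final, any disagreement — including one
involving "undeterminable" — goes to a third reviewer whose verdict stands.
A disagreement without a third verdict is a hard error naming the patient.
The previous flag is OR-ed across reviewers (conservative exclusion of
prevalent cases), and the true-case set is the "yes" verdicts excluding
previous cases by default, since only incident cases are validated.
Undeterminable cases are representable although the validated dataset
contained none.

## Metrics

Sensitivity and PPV are percentages of integer counts; a metric whose
denominator is zero is undefined and rendered as the literal string "NA" in
CSV output.  The default confidence interval is the Wald (normal
approximation) interval on the percentage scale, truncated to [0, 100],
with z = Φ⁻¹(0.975) ≈ 1.959964 at the default 95% level: this is the
interval the validated performance table was computed with, and the
in-package implementation reproduces every printed interval exactly,
including the degenerate zero-width intervals at p̂ ∈ {0, 1} and the fully
truncated (0, 100) interval at (1, 2).  Wilson and Clopper–Pearson
intervals are available through statsmodels for users who prefer intervals
with better small-sample coverage.  Rounding is half-up to two decimals and
happens at render time only.

The published table's true-case denominators (117, 59, 56, 30, 44 for
Hashimoto's, IBD, ITP, RA, T1D) are not printed directly; each was
back-solved from confirmed/sensitivity pairs and verified consistent across
every row of its disease block.  One published cell is internally
inconsistent: the IBD outpatient-code row (row 12) prints sensitivity 18.64
with confirmed = 32, which implies 54.24 against the block's denominator —
row 11's value appears to have been repeated.  The package computes from
counts and deliberately does not reproduce that cell; it is marked as an
anomaly in the reference table.

## Algorithm selection

The final composite is chosen by enumerating every non-empty component
subset (flag set = union of component flag sets), keeping those with PPV ≥
the floor (default 70%), and maximizing sensitivity; ties break toward
higher PPV, then fewer components, then lexicographically smaller id
tuples.  Exhaustive enumeration (capped at 20 components; the shipped
libraries have ≤ 12, i.e. ≤ 4095 subsets) makes the selection rule exact.
The floor comparison is done on integer cross-products (100·confirmed ≥
floor·valid) to avoid floating-point edge cases.  A
sensitivity–PPV Pareto frontier over all subsets is returned alongside the
choice, and a `per_component_filter` mode instead keeps every component
whose individual PPV meets the floor — both plausible readings of how such
final algorithms get assembled in practice.  The published final
memberships themselves cannot be re-derived here: that would require the
patient-level overlap structure of the source database, which is not
available; the selector is validated by property tests and small-instance
enumeration oracles instead.

## Synthetic data

The generator emulates the structure the pipeline assumes, not the source
population.  Each patient is a case with the scenario prevalence; cases
draw a per-channel emission (channel = one component's source × matcher),
emitting 1 + Poisson(λ) records on distinct dates within 180 days of a
per-case onset; non-cases emit false-coded records per channel at the
false-coding rate, uniform over the study window; everyone receives
Poisson-distributed background visits with distractor content that matches
no shipped rule.  Record content is synthesized to satisfy exactly its own
channel's matcher (synonym embedded in distractor text, or a
pattern-conforming code), so channels stay independent and the closed forms
below are exact.  Prevalent cases (probability `previous_case_fraction`)
receive an extra matching record more than a washout before onset and are
flagged previous by both reviewers.  Adjudication emits two primary
verdicts (each flipped with probability `adjudication_error`) plus a third,
truth-valued verdict for arbitration.  Output is deterministic given the
seed, down to bytes on disk.

For a channel with case emission q_t, false-coding rate q_f, threshold m
and record-count tail p_m = P(1 + Poisson(λ) ≥ m), evaluated against the
non-previous pool with prevalence π′ = π(1−f)/(1−πf):

    E[sensitivity] = q_t·p_m
    E[PPV] = π′·q_t·p_m / (π′·q_t·p_m + (1−π′)·q_f·p_m)

The packaged scenario uses the twelve ITP channels over a 2010–2021 window,
1.2% prevalence, λ = 1.5, and emission parameters spanning component PPVs
from roughly 17% to 100% — the spread seen across the validated component
algorithms (marginals only; overlaps are not calibrated).  What passing
recovery tests show is therefore that the engine, the evaluation module and
the generator agree with each other under independence; they say nothing
about correlated real-world coding behaviour, visit seasonality, or
source-specific documentation habits, none of which are modelled.

## Problem sizes and numerical notes

The default test run evaluates: the full published table (53 rows) exactly;
200 randomized 50-patient instances against a brute-force evaluator
oracle; 120 random ≤ 6-component selection instances against a
Fraction-arithmetic enumeration oracle; and the packaged scenario at
20,000 patients, where each channel's empirical sensitivity and PPV must
fall within 3 binomial standard errors of the closed forms.  Note that a
3-SE band applied to 24 statistics jointly has a ≈ 6% chance of at least
one excursion under the null, so this check is meaningful only at the
packaged scenario's fixed seed, which is part of the shipped conditions.
Hypothesis-based property tests run derandomized.

## Known limitations

* Rules are diagnosis-only: no medication, laboratory, or imaging
  components, which caps achievable sensitivity for biomarker-dependent
  diseases such as RA.
* Substring term matching has no negation or context handling.
* Record linkage across identifier systems is out of scope; the registry
  identifier is taken as already unified.
* Specificity and NPV are not computed: the validation universe is the
  adjudicated pool, and no population-scale adjudicated negatives exist.
* The incident/washout semantics resolve an ambiguity (index at composite
  satisfaction, evidence scanned at threshold one) that other
  implementations may resolve differently; both knobs that interact with
  it (`strict_washout`, `any_admission`) are explicit.
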