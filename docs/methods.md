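# Methods

This note documents the model, the reasoning procedure, the numerical and
design choices, what the synthetic data does and does not emulate, and known
limitations. It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Phenotype model

A phenotype is any documentable property of an organism; a phenotype *class*
is the abstract property (weight) instantiated by concrete phenotypes (this
patient's weight). Classes are **single** (directly observable),
**combined** (a Boolean combination of other phenotypes) or **derived** (a
new value computed by a formula), each in a **non-restricted** variant (all
instances allowed) and **restricted** variants (instances limited by a value
restriction or Boolean expression). A restricted class has exactly one
non-restricted parent; multiple inheritance is rejected — every algorithm we
have modelled uses single-parent patterns, and single parenthood is what
makes the report's non-restricted/restricted pairing well-defined.

Four primitive datatypes are supported: decimal, string, boolean, date.
Complex source types map onto them (FHIR Quantity → decimal + unit string,
code → string). Decimal values are `decimal.Decimal` end to end: clinical
cut-offs are exact numbers and must not be blurred by binary floats.
Boundary semantics are literal: `>= 125` includes 125, `> 0` excludes 0.
Units are verbatim strings with no conversion algebra — a mismatch between a
class unit and a data item's unit is a hard error, because no published
conversion rules exist for the general case and a silent conversion would be
a clinical-safety hazard.

### Validation and the dependency graph

`validate_model` returns diagnostics (class name + rule) rather than
raising, so a whole specification can be audited before deployment. The
dependency graph (via `networkx`) has edges: restricted-single → parent;
restricted-combined → each expression atom; derived → each variable class;
restricted-derived → parent; and additionally non-restricted-combined → each
of its restricted subclasses. The last edge kind is ours: a combined class
used as a formula variable contributes the *score* of an inferred subclass,
so the formula genuinely depends on those subclasses — without the edge, a
cycle (formula uses combined class whose subclass tests the formula's own
restricted result) would pass validation and undermine the termination
argument. Acyclicity is required; a topological order therefore exists for
every valid model (property-tested on random models).

## Expressions and formulas

Boolean expressions: infix `AND`/`OR`/`NOT` (case-insensitive), parentheses,
class-name atoms; `AND` binds tighter than `OR`. Evaluation is Kleene
three-valued — during reasoning an absent membership is *unknown*, and a
missing value never satisfies nor violates a restriction. DNF conversion
pushes negations to atoms, distributes conjunctions, drops contradictory
conjunctions and orders everything deterministically; expressions whose DNF
would exceed 4096 conjunctions are refused (the decision-tree export must
stay tractable). Equivalence with a truth-table oracle is property-tested.

Formulas: decimals, variables (`$Name` binds the record date rather than the
value), `+ − * / ^` (power binds tightest, right-associative), comparisons,
and functions `GT`, `LT`, `EQ`, `DATEDIFF`, `ABS`, `MIN`, `MAX`, `IF`;
custom functions can be registered. `GT(a, b)` returns 1/0/−1 for
greater/equal/less and −1 when an operand is missing. `LT`/`EQ` mirror that
missing-operand convention; this generalisation beyond `GT` is our choice
(the convention is only documented for `GT`) and is flagged here
deliberately. `DATEDIFF`/`ABS`/`MIN`/`MAX` instead *propagate* missing
(return no value) — returning −1 from an arithmetic function would be a
plausible-looking wrong number. Outside missing-tolerant functions, a
missing operand is an error.

Aggregates: `COUNT` of an empty item list is 0 — absence is observable, and
"count = 0" restrictions are precisely how negative criteria (no T1DM
diagnosis) are modelled positively. All other aggregates over an empty list
are missing. `FIRST`/`LAST` require record dates and break date ties by
source id (then formatted value): determinism over arbitrary server return
order.

## The reasoning loop

Ingestion builds one single-phenotype instance per class (aggregate applied)
and one composite instance per subject per run; there is no longitudinal
windowing — the engine computes a phenotype for the data snapshot it is
given. Several items for a non-aggregated class are a hard error: silently
picking one would hide a data problem the modeller should resolve with an
aggregate.

Each loop iteration runs classification to an internal fixpoint (combined
classes may reference combined classes inferred in the same step), then
marks derived classes *eligible* — all `required` variables bound and at
least one variable bound — and calculates eligible formulas. The
`required`-flag rule resolves a real tension: eligibility is supposed to
mean "all variable values are present", yet `GT` is explicitly
missing-tolerant. Marking the two medication variables of the bundled T2DM
model optional reproduces both canonical scenarios: with no medications at
all the comparison is never calculated (no case-1 path), while with one
medication missing it would still evaluate to −1. The loop stops when no
eligible derived class awaits calculation, giving the `|NDeP| + 1` iteration
bound (each continuing iteration calculates ≥ 1 new derived instance).

Negation is settled last: during the loop, absent memberships are unknown,
which keeps inference monotone (memberships only grow, order-independence is
property-tested by shuffling the class registry). A terminal closed-world
classification pass then treats absent memberships as false, firing
`NOT`-atoms. Limitation: memberships added by the terminal pass do not
re-trigger calculation; a model whose formula depends (via a score) on an
absence-dependent combined class will leave that formula uncalculated. None
of the bundled models has this shape, and the validator's dependency graph
makes the shape visible.

When several scored subclasses of one combined class hold simultaneously,
the maximum score feeds the formula (deterministic; matches
worst-severity-score semantics of clinical scores). Overlapping case
classes are reported in full — dropping any would be lossy; the bundled T2DM
cases are mutually exclusive by construction.

## FHIR mapping

R4 JSON only, as plain dicts. Query generation: codes render as
`system/code`, OR-joined by commas on the `code` parameter; `COUNT` →
`_summary=count`; `FIRST`/`LAST` → `_sort` on the resource's date parameter
plus `_count=1`. Date attributes are fixed per resource type — Observation
`effectiveDateTime`, Condition `recordedDate` (fallback `onsetDateTime`),
MedicationStatement `effectiveDateTime`/`effectivePeriod.start` — and the
sort parameters `date`/`recorded-date`/`effective` correspondingly; only the
MedicationStatement sort parameter is attested in print, the other two are
our convention. Quantity values render as `gt75||kg` (no code system) while
the parser also accepts the `//` dialect seen in print. Conditions and
MedicationStatements extract as dated presence items (boolean true):
diagnosis/medication logic needs only existence and date. There is no HTTP
client in the core; bundles are read from files or memory, keeping the
engine testable at desk scale.

## Synthetic data

`default_scenarios(n, seed)` cycles through the five case labels plus
"none"; every scenario is an independent RNG stream, so bundles are
byte-identical across calls. Value ranges are clinically plausible for the
thresholds they must clear or stay under (abnormal fasting glucose drawn
from 125–400 mg/dL, normal from 70–124; random glucose abnormal ≥ 200;
HbA1c abnormal 6.5–14 %; diagnosis counts 1–3; physician-diagnosis counts
2–5 for case 5; medication date offsets 1–200 days). "None" patients come in
three variants: healthy labs, a T1DM patient, and a T2DM diagnosis without
abnormal labs or medications.

What a green generator/reasoner agreement test establishes: extraction,
aggregation, classification, calculation and the closed-world pass jointly
recover the intended label on well-formed, single-subject, one-item-per-lab
bundles. What it does not establish: behaviour on real EHR data — duplicate
or conflicting observations, missing units, multiple encounters, coding
variants (ICD-10), or free-text — none of which the generator emulates.

## T2DM fixture provenance

The eight data elements, the COUNT/FIRST aggregates, the thresholds glucose
≥ 125 mg/dL, physician-diagnosis ≥ 2, diagnosis-absent = 0, the `GT` date
comparison with the `= 1` restriction, the three-way abnormal-lab
disjunction, and the full case-1 and case-3 expressions follow the published
description of the algorithm. The case-2, case-4 and case-5 expressions are
*reconstructed* from the PheKB flowchart the algorithm mirrors (no prose
spells them out) and should be treated as this package's reading of it; the
random-glucose (≥ 200 mg/dL) and HbA1c (≥ 6.5 %) cut-offs are likewise the
PheKB values. Result coding uses one observation code
(`t2dm_case_calculated`) plus one value code per case under
`https://www.smith.care/phenoman/t2dm_case_selection_algorithm`.

## Decision-tree export

Literals within each conjunction are ordered by first appearance of their
atom across the subclasses' DNFs (registry order), so paths that share
leading decisions share nodes and the path set of each leaf class equals its
expression's DNF (tested against the DNF directly). GraphML output carries
topology and labels only; layout belongs to the viewer.
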