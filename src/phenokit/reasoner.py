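"""The multistage classification–calculation reasoning loop.

Data about one subject is first turned into an *instance model*: one single
phenotype instance per single-phenotype class (its value attached via
``has_value``, aggregates already applied) and one composite instance that
ties all instances together via ``has_part``. The engine then alternates two
steps until a fixpoint:

1. **Classification** — instances are assigned to restricted classes:
   single instances to restricted-single classes whose value restriction they
   satisfy; the composite instance to restricted-combined classes whose
   Boolean expression evaluates to true under the current memberships; the
   composite instance is also marked eligible for derived classes whose
   formula variables are available; derived instances to restricted-derived
   classes by value restriction.
2. **Calculation** — the formula of every eligible, not-yet-calculated
   derived class is evaluated on its variable bindings (single-phenotype
   values or dates, or scores of inferred restricted-combined subclasses) and
   the result becomes a new derived instance.

The loop stops when classification marks no derived class that still awaits
calculation. During the loop an absent membership counts as *unknown*
(Kleene semantics), which keeps inference monotone; a final closed-world
classification pass then settles NOT-atoms and absence-dependent classes.
Termination is bounded: every continuing iteration calculates at least one
new derived class, so the loop runs at most ``|derived classes| + 1`` times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple, Union

from . import fhir as _fhir
from .errors import MultipleItemsError, UnitMismatchError
from .expressions import apply_aggregate, evaluate_boolean, evaluate_formula
from .model import (
    CombinedPhenotypeClass,
    DerivedPhenotypeClass,
    PhenotypeModel,
    RestrictedCombinedClass,
    RestrictedDerivedClass,
    RestrictedSingleClass,
    SinglePhenotypeClass,
    restriction_satisfied,
)
from .values import AggregateFunction, DataType, PhenotypeValue, Scalar

__all__ = [
    "SinglePhenotypeInstance",
    "ReasonerState",
    "InferredPhenotype",
    "ReasonerResult",
    "ingest",
    "records_from_bundle",
    "classification_step",
    "calculation_step",
    "reason",
    "reason_bundle",
    "report",
]

REPORT_HEADER = ("Type", "Non-restricted", "Restricted")


@dataclass(frozen=True)
class SinglePhenotypeInstance:
    """One single-phenotype instance: class name, (aggregated) value, and the
    number of source items it aggregates."""

    class_name: str
    value: Optional[PhenotypeValue]
    source_count: int = 0


@dataclass
class ReasonerState:
    """Mutable state of one reasoning run over one composite instance."""

    model: PhenotypeModel
    subject: str
    singles: Dict[str, SinglePhenotypeInstance] = field(default_factory=dict)
    derived: Dict[str, PhenotypeValue] = field(default_factory=dict)
    memberships: Set[str] = field(default_factory=set)
    membership_iteration: Dict[str, int] = field(default_factory=dict)
    eligible: Set[str] = field(default_factory=set)
    calculated: Set[str] = field(default_factory=set)
    derived_iteration: Dict[str, int] = field(default_factory=dict)
    iterations: int = 0
    log: List[str] = field(default_factory=list)


@dataclass(frozen=True)
class InferredPhenotype:
    """One inferred class (or calculated derived instance) with its value."""

    name: str
    kind: str  # "single" | "combined" | "derived"
    value: Optional[PhenotypeValue]
    iteration: int


@dataclass(frozen=True)
class ReasonerResult:
    """Outcome of one reasoning run."""

    subject: str
    inferred: Tuple[InferredPhenotype, ...]
    memberships: frozenset
    derived_values: Dict[str, PhenotypeValue]
    report_rows: Tuple[Tuple[str, str, Tuple[str, ...]], ...]
    iterations: int

    def case_memberships(self, ncop_name: str) -> Tuple[str, ...]:
        """Inferred restricted subclasses of one combined class (sorted)."""
        return tuple(
            sorted(
                m
                for m in self.memberships
                if m in {c.name for c in _subclasses(self, ncop_name)}
            )
        )

    _model: Optional[PhenotypeModel] = field(default=None, compare=False, repr=False)


def _subclasses(result: ReasonerResult, ncop_name: str):
    if result._model is None:
        return []
    return result._model.subclasses_of(ncop_name)


# ---------------------------------------------------------------------------
# Ingest
# ---------------------------------------------------------------------------


def ingest(
    model: PhenotypeModel,
    records: Mapping[str, Sequence[PhenotypeValue]],
    subject: str,
) -> ReasonerState:
    """Build the instance model from per-class item lists.

    Aggregates are applied here. COUNT classes are always instantiated, even
    with zero items (an observable absence); other aggregates over zero items
    and non-aggregated classes without items yield a missing value. A
    non-aggregated class receiving several items is a hard error — silently
    picking one would hide a data problem; the modeller should attach an
    aggregate instead. An item whose unit contradicts the class unit is
    likewise an error (units are verbatim, no conversion is attempted).
    """
    state = ReasonerState(model=model, subject=subject)
    for nsip in model.single_classes():
        items = list(records.get(nsip.name, ()))
        for item in items:
            if nsip.unit and item.unit and nsip.unit != item.unit:
                raise UnitMismatchError(
                    f"{nsip.name}: item unit {item.unit!r} != class unit {nsip.unit!r}"
                )
        if nsip.aggregate is not None:
            value = apply_aggregate(nsip.aggregate, items)
            if value is not None and nsip.aggregate is AggregateFunction.COUNT:
                pass  # COUNT is unitless
        elif len(items) > 1:
            raise MultipleItemsError(
                f"{nsip.name}: {len(items)} items for a class without an aggregate "
                "function; define an aggregate (e.g., FIRST or LAST) on the class"
            )
        else:
            value = items[0] if items else None
        state.singles[nsip.name] = SinglePhenotypeInstance(
            class_name=nsip.name, value=value, source_count=len(items)
        )
    return state


def records_from_bundle(
    model: PhenotypeModel, bundle_or_resources
) -> Dict[str, List[PhenotypeValue]]:
    """Extract per-class item lists from a FHIR bundle (or resource list)."""
    resources = _fhir.bundle_resources(bundle_or_resources)
    return {
        nsip.name: _fhir.extract_items(resources, nsip)
        for nsip in model.single_classes()
    }


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def _atom_truth(state: ReasonerState, name: str, closed_world: bool):
    if name in state.memberships:
        return True
    return False if closed_world else None


def _variable_bound(state: ReasonerState, var) -> bool:
    cls = state.model[var.name]
    if isinstance(cls, SinglePhenotypeClass):
        inst = state.singles.get(var.name)
        if inst is None or inst.value is None:
            return False
        if var.use_date:
            return inst.value.record_date is not None
        return True
    if isinstance(cls, CombinedPhenotypeClass):
        return any(
            sub.name in state.memberships and sub.score is not None
            for sub in state.model.subclasses_of(var.name)
            if isinstance(sub, RestrictedCombinedClass)
        )
    return False


def classification_step(state: ReasonerState, closed_world: bool = False) -> Set[str]:
    """One classification step; returns the memberships it added.

    Iterates internally to a fixpoint, because restricted-combined classes
    may reference other restricted-combined classes inferred in the same
    step. With ``closed_world=True`` absent memberships count as false
    instead of unknown — used only for the terminal pass. Calling the step
    again on unchanged state adds nothing (idempotent).
    """
    model = state.model
    added_total: Set[str] = set()
    while True:
        added: Set[str] = set()
        for rsip in model.restricted_single_classes():
            if rsip.name in state.memberships:
                continue
            inst = state.singles.get(rsip.parent)
            if inst is None:
                continue
            if restriction_satisfied(rsip.restriction, inst.value) is True:
                added.add(rsip.name)
        for rdep in model.restricted_derived_classes():
            if rdep.name in state.memberships:
                continue
            value = state.derived.get(rdep.parent)
            if value is None:
                continue
            if restriction_satisfied(rdep.restriction, value) is True:
                added.add(rdep.name)
        current = state.memberships | added
        for rcop in model.restricted_combined_classes():
            if rcop.name in current:
                continue
            truth = {
                atom: (True if atom in current else (False if closed_world else None))
                for atom in _expression_atoms(rcop)
            }
            if evaluate_boolean(rcop.expression, truth) is True:
                added.add(rcop.name)
        if not added:
            break
        state.memberships |= added
        for name in added:
            state.membership_iteration.setdefault(name, state.iterations)
        added_total |= added
    # step 1c: mark derived classes whose variables are available
    state.eligible = {
        ndep.name
        for ndep in model.derived_classes()
        if all(_variable_bound(state, v) for v in ndep.variables if v.required)
        and any(_variable_bound(state, v) for v in ndep.variables)
    }
    if added_total:
        state.log.append(
            f"iteration {state.iterations}: classified {sorted(added_total)}"
        )
    return added_total


def _expression_atoms(rcop: RestrictedCombinedClass):
    from .expressions import boolean_atoms

    return boolean_atoms(rcop.expression)


# ---------------------------------------------------------------------------
# Calculation
# ---------------------------------------------------------------------------


def _bind_variables(state: ReasonerState, ndep: DerivedPhenotypeClass):
    bindings: Dict[str, Optional[PhenotypeValue]] = {}
    for var in ndep.variables:
        cls = state.model[var.name]
        if isinstance(cls, SinglePhenotypeClass):
            inst = state.singles.get(var.name)
            bindings[var.name] = inst.value if inst else None
        else:  # combined: the score of the inferred restricted subclass
            scores = [
                sub.score
                for sub in state.model.subclasses_of(var.name)
                if isinstance(sub, RestrictedCombinedClass)
                and sub.name in state.memberships
                and sub.score is not None
            ]
            if not scores:
                bindings[var.name] = None
            else:
                # several scored subclasses may hold at once; use the maximum
                # (deterministic; matches worst-severity score semantics)
                bindings[var.name] = PhenotypeValue.decimal(max(scores))
    return bindings


def calculation_step(state: ReasonerState) -> Set[str]:
    """Calculate formulas of eligible derived classes; returns the new ones."""
    new: Set[str] = set()
    for name in sorted(state.eligible - state.calculated):
        ndep = state.model[name]
        bindings = _bind_variables(state, ndep)
        raw = evaluate_formula(ndep.formula, bindings)
        state.calculated.add(name)
        if raw is None:
            continue  # missing-propagating formula produced no value
        state.derived[name] = _as_phenotype_value(raw, ndep)
        state.derived_iteration[name] = state.iterations
        new.add(name)
    if new:
        state.log.append(
            f"iteration {state.iterations}: calculated "
            + ", ".join(f"{n} = {state.derived[n].formatted()}" for n in sorted(new))
        )
    return new


def _as_phenotype_value(raw: Scalar, ndep: DerivedPhenotypeClass) -> PhenotypeValue:
    if isinstance(raw, bool):
        return PhenotypeValue.boolean(raw)
    if isinstance(raw, Decimal):
        return PhenotypeValue.decimal(raw, unit=ndep.unit)
    if isinstance(raw, str):
        return PhenotypeValue.string(raw)
    return PhenotypeValue.date(raw)


# ---------------------------------------------------------------------------
# The loop
# ---------------------------------------------------------------------------


def reason(
    model: PhenotypeModel,
    records: Mapping[str, Sequence[PhenotypeValue]],
    subject: str,
) -> ReasonerResult:
    """Run the full classification–calculation loop for one subject."""
    state = ingest(model, records, subject)
    while True:
        state.iterations += 1
        classification_step(state)
        pending = state.eligible - state.calculated
        if not pending:
            break
        if not calculation_step(state):
            break  # eligible formulas yielded nothing new; fixpoint reached
    # terminal pass: settle NOT-atoms / absence with closed-world semantics
    classification_step(state, closed_world=True)
    return _build_result(state)


def reason_bundle(
    model: PhenotypeModel, bundle, subject: Optional[str] = None
) -> ReasonerResult:
    """Convenience wrapper: extract records from a FHIR bundle, then reason.

    The subject is taken from the first resource's subject reference when not
    given explicitly.
    """
    resources = _fhir.bundle_resources(bundle)
    if subject is None:
        for res in resources:
            ref = (res.get("subject") or {}).get("reference")
            if ref:
                subject = ref
                break
        else:
            subject = "unknown"
    return reason(model, records_from_bundle(model, resources), subject)


def _build_result(state: ReasonerState) -> ReasonerResult:
    model = state.model
    inferred: List[InferredPhenotype] = []
    for name in sorted(state.memberships):
        cls = model[name]
        if isinstance(cls, RestrictedSingleClass):
            inst = state.singles.get(cls.parent)
            inferred.append(
                InferredPhenotype(
                    name, "single", inst.value if inst else None,
                    state.membership_iteration.get(name, state.iterations),
                )
            )
        elif isinstance(cls, RestrictedCombinedClass):
            value = PhenotypeValue.decimal(cls.score) if cls.score is not None else None
            inferred.append(
                InferredPhenotype(
                    name, "combined", value,
                    state.membership_iteration.get(name, state.iterations),
                )
            )
        else:
            inferred.append(
                InferredPhenotype(
                    name, "derived", state.derived.get(cls.parent),
                    state.membership_iteration.get(name, state.iterations),
                )
            )
    for name, value in sorted(state.derived.items()):
        inferred.append(
            InferredPhenotype(
                name, "derived", value, state.derived_iteration.get(name, state.iterations)
            )
        )
    return ReasonerResult(
        subject=state.subject,
        inferred=tuple(inferred),
        memberships=frozenset(state.memberships),
        derived_values=dict(state.derived),
        report_rows=_report_rows(state),
        iterations=state.iterations,
        _model=model,
    )


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def _report_rows(state: ReasonerState) -> Tuple[Tuple[str, str, Tuple[str, ...]], ...]:
    model = state.model
    rows: List[Tuple[str, str, Tuple[str, ...]]] = []
    for cls in model.classes.values():
        if isinstance(cls, SinglePhenotypeClass):
            inst = state.singles.get(cls.name)
            if inst is None or inst.value is None:
                continue
            restricted = tuple(
                sub.name
                for sub in model.subclasses_of(cls.name)
                if sub.name in state.memberships
            )
            rows.append(("single", f"{cls.name} = {inst.value.formatted()}", restricted))
        elif isinstance(cls, DerivedPhenotypeClass):
            value = state.derived.get(cls.name)
            if value is None:
                continue
            restricted = tuple(
                sub.name
                for sub in model.subclasses_of(cls.name)
                if sub.name in state.memberships
            )
            rows.append(("derived", f"{cls.name} = {value.formatted()}", restricted))
        elif isinstance(cls, CombinedPhenotypeClass):
            restricted = tuple(
                sub.name
                for sub in model.subclasses_of(cls.name)
                if sub.name in state.memberships
            )
            if not restricted:
                continue
            rows.append(("combined", cls.name, restricted))
    return tuple(rows)


def report(result: ReasonerResult) -> Tuple[Tuple[str, str, Tuple[str, ...]], ...]:
    """Tabular reasoner report rows.

    One row per non-restricted class that has an instance: the class type
    (single / combined / derived), the class with its input or calculated
    value, and the restricted class names inferred for it.
    """
    return result.report_rows
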