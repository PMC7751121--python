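"""Phenotype class taxonomy and model validation.

A phenotype model is a registry of phenotype classes of six kinds:

* **NSiP** — non-restricted single phenotype: one atomic, directly observable
  property (e.g., fasting glucose), carrying codes, a datatype, a unit, an
  optional aggregate function and the FHIR resource type it is read from.
* **RSiP** — restricted single phenotype: an NSiP constrained to a value
  range (interval), an enumeration or a boolean flag (e.g.,
  ``Fasting_Glucose_ABNORMAL``: fasting glucose >= 125 mg/dL).
* **NCoP / RCoP** — combined phenotypes: an RCoP carries a Boolean expression
  over restricted classes and an optional score usable in formulas.
* **NDeP / RDeP** — derived phenotypes: an NDeP computes a new value by a
  mathematical formula from other phenotypes; RDePs restrict that value.

Restricted classes have exactly one non-restricted parent. Validation is
diagnostic-based: :func:`validate_model` returns a (possibly empty) list of
problems rather than raising, so a whole model can be checked before
deployment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date
from decimal import Decimal
from typing import Dict, FrozenSet, Iterator, List, Optional, Sequence, Tuple, Union
from urllib.parse import urlparse

import networkx as nx

from . import expressions as xp
from .errors import DataTypeMismatchError, ModelError
from .values import AggregateFunction, DataType, PhenotypeValue, Trilean, as_date, as_decimal

__all__ = [
    "Code",
    "ValueRestriction",
    "restriction_satisfied",
    "FormulaVariable",
    "SinglePhenotypeClass",
    "RestrictedSingleClass",
    "CombinedPhenotypeClass",
    "RestrictedCombinedClass",
    "DerivedPhenotypeClass",
    "RestrictedDerivedClass",
    "PhenotypeModel",
    "Diagnostic",
    "validate_model",
    "dependency_graph",
    "FHIR_RESOURCE_TYPES",
]

FHIR_RESOURCE_TYPES = ("Observation", "Condition", "MedicationStatement")

Bound = Union[Decimal, _date]


@dataclass(frozen=True)
class Code:
    """A terminology concept: system URI plus code identifier."""

    system: str
    code: str

    def __post_init__(self):
        if not self.code:
            raise ModelError("code must be non-empty")
        parsed = urlparse(self.system)
        if not parsed.scheme or not (parsed.netloc or parsed.path):
            raise ModelError(f"code system must be an absolute URI, got {self.system!r}")


@dataclass(frozen=True)
class ValueRestriction:
    """A constraint on values: an interval, an enumeration or a boolean flag.

    Interval bounds are decimals or dates; each bound carries its own
    inclusivity flag, so ``>= 125`` and ``> 0`` are both expressible and
    boundary semantics are literal. Comparison of decimals is exact.
    """

    kind: str  # "interval" | "enumeration" | "boolean-flag"
    min: Optional[Bound] = None
    max: Optional[Bound] = None
    min_inclusive: bool = True
    max_inclusive: bool = True
    allowed: Optional[FrozenSet] = None
    expected: bool = True  # boolean-flag target value

    def __post_init__(self):
        if self.kind not in ("interval", "enumeration", "boolean-flag"):
            raise ModelError(f"unknown restriction kind {self.kind!r}")
        if self.kind == "interval":
            if self.min is None and self.max is None:
                raise ModelError("interval restriction requires at least one bound")
            if self.min is not None and self.max is not None:
                if type(self.min) is not type(self.max):
                    raise ModelError("interval bounds must share a datatype")
                if self.min > self.max:
                    raise ModelError("interval min must not exceed max")
        if self.kind == "enumeration":
            if not self.allowed:
                raise ModelError("enumeration restriction requires allowed values")
            object.__setattr__(self, "allowed", frozenset(self.allowed))

    # -- operator-style constructors, mapping written thresholds literally ----

    @classmethod
    def ge(cls, bound) -> "ValueRestriction":
        return cls("interval", min=_as_bound(bound), min_inclusive=True)

    @classmethod
    def gt(cls, bound) -> "ValueRestriction":
        return cls("interval", min=_as_bound(bound), min_inclusive=False)

    @classmethod
    def le(cls, bound) -> "ValueRestriction":
        return cls("interval", max=_as_bound(bound), max_inclusive=True)

    @classmethod
    def lt(cls, bound) -> "ValueRestriction":
        return cls("interval", max=_as_bound(bound), max_inclusive=False)

    @classmethod
    def eq(cls, bound) -> "ValueRestriction":
        b = _as_bound(bound)
        return cls("interval", min=b, max=b)

    @classmethod
    def between(cls, lo, hi, min_inclusive=True, max_inclusive=True) -> "ValueRestriction":
        return cls(
            "interval",
            min=_as_bound(lo),
            max=_as_bound(hi),
            min_inclusive=min_inclusive,
            max_inclusive=max_inclusive,
        )

    @classmethod
    def enumeration(cls, allowed) -> "ValueRestriction":
        return cls("enumeration", allowed=frozenset(allowed))

    @classmethod
    def flag(cls, expected: bool = True) -> "ValueRestriction":
        return cls("boolean-flag", expected=expected)

    def compatible_with(self, datatype: DataType) -> bool:
        """Whether this restriction can apply to values of ``datatype``."""
        if self.kind == "boolean-flag":
            return datatype is DataType.BOOLEAN
        if self.kind == "enumeration":
            return datatype in (DataType.STRING, DataType.DECIMAL)
        bound = self.min if self.min is not None else self.max
        if isinstance(bound, Decimal):
            return datatype is DataType.DECIMAL
        return datatype is DataType.DATE


def _as_bound(x) -> Bound:
    if isinstance(x, _date):
        return x
    if isinstance(x, str):
        try:
            return as_decimal(x)
        except DataTypeMismatchError:
            return as_date(x)
    return as_decimal(x)


def restriction_satisfied(
    restriction: ValueRestriction,
    value: Union[PhenotypeValue, Decimal, _date, str, bool, None],
) -> Trilean:
    """Three-valued restriction check.

    Returns ``True``/``False`` for a present, type-compatible value and
    ``None`` (unknown) for a missing one — a missing value never satisfies
    nor violates a restriction. A datatype mismatch between the restriction
    and a present value signals a model/data inconsistency and raises
    :class:`DataTypeMismatchError`.
    """
    if value is None:
        return None
    v = value.value if isinstance(value, PhenotypeValue) else value
    if v is None:
        return None
    if restriction.kind == "boolean-flag":
        if not isinstance(v, bool):
            raise DataTypeMismatchError(f"boolean-flag restriction got {v!r}")
        return v is restriction.expected
    if restriction.kind == "enumeration":
        if isinstance(v, bool) or not isinstance(v, (str, Decimal)):
            raise DataTypeMismatchError(f"enumeration restriction got {v!r}")
        return v in restriction.allowed
    # interval
    bound = restriction.min if restriction.min is not None else restriction.max
    if isinstance(bound, Decimal):
        if isinstance(v, bool) or not isinstance(v, Decimal):
            raise DataTypeMismatchError(f"decimal interval restriction got {v!r}")
    elif not isinstance(v, _date):
        raise DataTypeMismatchError(f"date interval restriction got {v!r}")
    if restriction.min is not None:
        if v < restriction.min or (v == restriction.min and not restriction.min_inclusive):
            return False
    if restriction.max is not None:
        if v > restriction.max or (v == restriction.max and not restriction.max_inclusive):
            return False
    return True


# ---------------------------------------------------------------------------
# Phenotype classes
# ---------------------------------------------------------------------------


def _codes(codes) -> Tuple[Code, ...]:
    return tuple(c if isinstance(c, Code) else Code(**c) for c in (codes or ()))


@dataclass(frozen=True)
class SinglePhenotypeClass:
    """NSiP: a directly observable single phenotype (e.g., fasting glucose)."""

    name: str
    datatype: DataType = DataType.DECIMAL
    codes: Tuple[Code, ...] = ()
    unit: Optional[str] = None
    aggregate: Optional[AggregateFunction] = None
    fhir_resource_type: Optional[str] = None
    labels: Dict[str, str] = field(default_factory=dict, compare=False)
    descriptions: Dict[str, str] = field(default_factory=dict, compare=False)
    annotations: Dict[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "datatype", DataType(self.datatype))
        object.__setattr__(self, "codes", _codes(self.codes))
        if self.aggregate is not None:
            object.__setattr__(self, "aggregate", AggregateFunction(self.aggregate))

    @property
    def effective_datatype(self) -> DataType:
        """Datatype of the aggregated instance (COUNT always yields decimal)."""
        if self.aggregate is AggregateFunction.COUNT:
            return DataType.DECIMAL
        return self.datatype


@dataclass(frozen=True)
class RestrictedSingleClass:
    """RSiP: an NSiP constrained to a value range/enumeration/flag."""

    name: str
    parent: str
    restriction: ValueRestriction
    codes: Tuple[Code, ...] = ()
    labels: Dict[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "codes", _codes(self.codes))


@dataclass(frozen=True)
class CombinedPhenotypeClass:
    """NCoP: a combination of other phenotypes; its RCoP subclasses carry the
    combining Boolean expressions."""

    name: str
    codes: Tuple[Code, ...] = ()
    labels: Dict[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "codes", _codes(self.codes))


@dataclass(frozen=True)
class RestrictedCombinedClass:
    """RCoP: Boolean expression over restricted classes, optional score."""

    name: str
    parent: str
    expression: xp.BooleanExpr
    score: Optional[Decimal] = None
    codes: Tuple[Code, ...] = ()
    labels: Dict[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if isinstance(self.expression, str):
            object.__setattr__(self, "expression", xp.parse_boolean(self.expression))
        if self.score is not None:
            object.__setattr__(self, "score", as_decimal(self.score))
        object.__setattr__(self, "codes", _codes(self.codes))


@dataclass(frozen=True)
class FormulaVariable:
    """One variable of a derived phenotype's formula.

    ``required`` controls eligibility of the formula for calculation: the
    formula runs once every required variable is bound and at least one
    variable is bound overall. ``use_date`` marks variables whose record date
    (not value) feeds the formula, written ``$Name`` in formula text.
    """

    name: str
    required: bool = True
    use_date: bool = False


@dataclass(frozen=True)
class DerivedPhenotypeClass:
    """NDeP: a new property computed by a formula from other phenotypes."""

    name: str
    formula: xp.Formula
    variables: Tuple[FormulaVariable, ...]
    datatype: DataType = DataType.DECIMAL
    unit: Optional[str] = None
    codes: Tuple[Code, ...] = ()
    labels: Dict[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if isinstance(self.formula, str):
            object.__setattr__(self, "formula", xp.parse_formula(self.formula))
        object.__setattr__(
            self,
            "variables",
            tuple(v if isinstance(v, FormulaVariable) else FormulaVariable(**v) for v in self.variables),
        )
        object.__setattr__(self, "datatype", DataType(self.datatype))
        object.__setattr__(self, "codes", _codes(self.codes))


@dataclass(frozen=True)
class RestrictedDerivedClass:
    """RDeP: restriction on a derived (calculated) value."""

    name: str
    parent: str
    restriction: ValueRestriction
    codes: Tuple[Code, ...] = ()
    labels: Dict[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "codes", _codes(self.codes))


PhenotypeClass = Union[
    SinglePhenotypeClass,
    RestrictedSingleClass,
    CombinedPhenotypeClass,
    RestrictedCombinedClass,
    DerivedPhenotypeClass,
    RestrictedDerivedClass,
]

_KIND = {
    SinglePhenotypeClass: "single",
    RestrictedSingleClass: "restricted-single",
    CombinedPhenotypeClass: "combined",
    RestrictedCombinedClass: "restricted-combined",
    DerivedPhenotypeClass: "derived",
    RestrictedDerivedClass: "restricted-derived",
}

RESTRICTED_KINDS = (RestrictedSingleClass, RestrictedCombinedClass, RestrictedDerivedClass)


@dataclass
class PhenotypeModel:
    """A registry of phenotype classes forming one phenotype specification."""

    name: str
    result_code_system: Optional[str] = None
    categories: Dict[str, str] = field(default_factory=dict)
    classes: Dict[str, PhenotypeClass] = field(default_factory=dict)

    def add(self, *cls: PhenotypeClass) -> "PhenotypeModel":
        for c in cls:
            existing = self.classes.get(c.name)
            if existing is not None and existing != c:
                raise ModelError(f"class {c.name!r} already defined differently")
            self.classes[c.name] = c
        return self

    def __contains__(self, name: str) -> bool:
        return name in self.classes

    def __getitem__(self, name: str) -> PhenotypeClass:
        try:
            return self.classes[name]
        except KeyError:
            raise ModelError(f"unknown phenotype class {name!r}") from None

    def _of_type(self, t) -> Iterator:
        return (c for c in self.classes.values() if isinstance(c, t))

    def single_classes(self) -> List[SinglePhenotypeClass]:
        return list(self._of_type(SinglePhenotypeClass))

    def restricted_single_classes(self) -> List[RestrictedSingleClass]:
        return list(self._of_type(RestrictedSingleClass))

    def combined_classes(self) -> List[CombinedPhenotypeClass]:
        return list(self._of_type(CombinedPhenotypeClass))

    def restricted_combined_classes(self) -> List[RestrictedCombinedClass]:
        return list(self._of_type(RestrictedCombinedClass))

    def derived_classes(self) -> List[DerivedPhenotypeClass]:
        return list(self._of_type(DerivedPhenotypeClass))

    def restricted_derived_classes(self) -> List[RestrictedDerivedClass]:
        return list(self._of_type(RestrictedDerivedClass))

    def subclasses_of(self, name: str) -> List[PhenotypeClass]:
        """Restricted subclasses of a non-restricted class, in registry order."""
        return [
            c
            for c in self.classes.values()
            if isinstance(c, RESTRICTED_KINDS) and c.parent == name
        ]

    def kind_of(self, name: str) -> str:
        return _KIND[type(self[name])]


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Diagnostic:
    """One validation finding: the class concerned, the rule violated, text."""

    class_name: str
    rule: str
    message: str

    def __str__(self) -> str:
        return f"[{self.class_name}] {self.rule}: {self.message}"


def validate_model(model: PhenotypeModel) -> List[Diagnostic]:
    """Validate a whole model; empty list means every invariant holds.

    Checks reference resolution, restricted-class/parent compatibility,
    formula variable declarations, score availability for combined classes
    used as formula variables, and acyclicity of the dependency graph.
    """
    out: List[Diagnostic] = []

    def bad(name: str, rule: str, msg: str) -> None:
        out.append(Diagnostic(name, rule, msg))

    for cls in model.classes.values():
        if isinstance(cls, SinglePhenotypeClass):
            if cls.fhir_resource_type not in FHIR_RESOURCE_TYPES:
                bad(cls.name, "fhir-resource-type", f"must be one of {FHIR_RESOURCE_TYPES}, got {cls.fhir_resource_type!r}")
        elif isinstance(cls, RestrictedSingleClass):
            parent = model.classes.get(cls.parent)
            if not isinstance(parent, SinglePhenotypeClass):
                bad(cls.name, "unresolved-reference", f"parent {cls.parent!r} is not a known single phenotype class")
            elif not cls.restriction.compatible_with(parent.effective_datatype):
                bad(cls.name, "restriction-datatype", f"restriction incompatible with parent datatype {parent.effective_datatype.value}")
        elif isinstance(cls, RestrictedCombinedClass):
            parent = model.classes.get(cls.parent)
            if not isinstance(parent, CombinedPhenotypeClass):
                bad(cls.name, "unresolved-reference", f"parent {cls.parent!r} is not a known combined phenotype class")
            for atom in sorted(xp.boolean_atoms(cls.expression)):
                ref = model.classes.get(atom)
                if ref is None:
                    bad(cls.name, "unresolved-reference", f"expression references unknown class {atom!r}")
                elif not isinstance(ref, RESTRICTED_KINDS):
                    bad(cls.name, "expression-atom-kind", f"expression atom {atom!r} is not a restricted class")
        elif isinstance(cls, DerivedPhenotypeClass):
            declared = {v.name for v in cls.variables}
            for var in sorted(xp.formula_variables(cls.formula)):
                if var not in declared:
                    bad(cls.name, "undeclared-variable", f"formula variable {var!r} not in variable list")
            if len(declared) != len(cls.variables):
                bad(cls.name, "duplicate-variable", "variable list contains duplicates")
            for v in cls.variables:
                ref = model.classes.get(v.name)
                if ref is None:
                    bad(cls.name, "unresolved-reference", f"variable {v.name!r} unknown")
                elif isinstance(ref, CombinedPhenotypeClass):
                    subs = model.subclasses_of(ref.name)
                    if not subs:
                        bad(cls.name, "score-missing", f"combined variable {v.name!r} has no restricted subclasses")
                    elif any(s.score is None for s in subs):
                        bad(cls.name, "score-missing", f"combined variable {v.name!r} has subclasses without score values")
                elif not isinstance(ref, SinglePhenotypeClass):
                    bad(cls.name, "variable-kind", f"variable {v.name!r} must be a single or combined phenotype class")
        elif isinstance(cls, RestrictedDerivedClass):
            parent = model.classes.get(cls.parent)
            if not isinstance(parent, DerivedPhenotypeClass):
                bad(cls.name, "unresolved-reference", f"parent {cls.parent!r} is not a known derived phenotype class")
            elif not cls.restriction.compatible_with(parent.datatype):
                bad(cls.name, "restriction-datatype", f"restriction incompatible with parent datatype {parent.datatype.value}")

    if not any(d.rule == "unresolved-reference" for d in out):
        graph = dependency_graph(model)
        try:
            cycle = nx.find_cycle(graph)
            names = " -> ".join(str(a) for a, _ in cycle)
            bad(cycle[0][0], "dependency-cycle", f"cyclic dependency: {names}")
        except nx.NetworkXNoCycle:
            pass
    return out


def dependency_graph(model: PhenotypeModel) -> "nx.DiGraph":
    """Directed graph of class dependencies (edges point at prerequisites).

    Edges: RSiP -> parent NSiP; RCoP -> each expression atom; NDeP -> each
    variable class; RDeP -> parent NDeP; NCoP -> each RCoP subclass (a
    combined class's score is only available once a subclass is inferred, so
    formulas using the NCoP depend on those subclasses — without these edges
    a score/expression cycle would go undetected).

    Acyclicity of this graph underwrites termination of the reasoning loop.
    """
    g = nx.DiGraph()
    g.add_nodes_from(model.classes)
    for cls in model.classes.values():
        if isinstance(cls, RestrictedSingleClass) and cls.parent in model:
            g.add_edge(cls.name, cls.parent)
        elif isinstance(cls, RestrictedCombinedClass):
            if cls.parent in model:
                g.add_edge(cls.parent, cls.name)  # NCoP depends on its RCoPs
            for atom in xp.boolean_atoms(cls.expression):
                if atom in model:
                    g.add_edge(cls.name, atom)
        elif isinstance(cls, DerivedPhenotypeClass):
            for v in cls.variables:
                if v.name in model:
                    g.add_edge(cls.name, v.name)
        elif isinstance(cls, RestrictedDerivedClass) and cls.parent in model:
            g.add_edge(cls.name, cls.parent)
    return g


def topological_order(model: PhenotypeModel) -> List[str]:
    """Dependencies-first class ordering; raises ModelError on a cycle."""
    g = dependency_graph(model)
    try:
        return list(reversed(list(nx.topological_sort(g))))
    except nx.NetworkXUnfeasible as exc:
        raise ModelError("dependency graph contains a cycle") from exc
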