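"""Random small phenotype models with an independent evaluation oracle.

Models are *stratified*: restricted-combined expressions reference only
restricted-single and restricted-derived atoms, and derived-class variables
reference only single classes. Under stratification the engine's iterative
fixpoint must coincide with a direct one-shot evaluation, which this module
performs with its own tiny evaluator (no engine code on the oracle path
beyond AST field access).
"""

import random
from decimal import Decimal

from phenokit.expressions import And, Atom, Not, Or
from phenokit.model import (
    CombinedPhenotypeClass,
    DerivedPhenotypeClass,
    FormulaVariable,
    PhenotypeModel,
    RestrictedCombinedClass,
    RestrictedDerivedClass,
    RestrictedSingleClass,
    SinglePhenotypeClass,
    ValueRestriction,
)
from phenokit.values import PhenotypeValue


def random_model_and_records(rng: random.Random):
    """A random valid stratified model plus per-class item lists.

    Structure: 2-4 decimal single classes (some values missing), one
    threshold restriction each; 0-2 derived classes summing or differencing
    two singles, each with one threshold restriction; one combined class with
    1-3 scored restricted subclasses whose expressions are AND/OR/NOT
    combinations of up to 4 restricted atoms.
    """
    model = PhenotypeModel(name="random")
    records = {}
    thresholds = {}

    n_single = rng.randint(2, 4)
    singles = []
    for i in range(n_single):
        name = f"S{i}"
        model.add(SinglePhenotypeClass(name=name, fhir_resource_type="Observation"))
        singles.append(name)
        if rng.random() < 0.8:
            records[name] = [PhenotypeValue.decimal(rng.randint(0, 100))]
        else:
            records[name] = []
        t = rng.randint(10, 90)
        thresholds[f"{name}_HIGH"] = ("single", name, t)
        model.add(RestrictedSingleClass(f"{name}_HIGH", name, ValueRestriction.ge(t)))

    restricted_atoms = [f"{s}_HIGH" for s in singles]

    for j in range(rng.randint(0, 2)):
        name = f"D{j}"
        a, b = rng.sample(singles, 2)
        op = rng.choice(("+", "-"))
        model.add(
            DerivedPhenotypeClass(
                name=name,
                formula=f"{a} {op} {b}",
                variables=(FormulaVariable(a), FormulaVariable(b)),
            )
        )
        t = rng.randint(-50, 150)
        thresholds[f"{name}_HIGH"] = ("derived", (a, op, b), t)
        model.add(RestrictedDerivedClass(f"{name}_HIGH", name, ValueRestriction.ge(t)))
        restricted_atoms.append(f"{name}_HIGH")

    model.add(CombinedPhenotypeClass(name="C"))
    for k in range(rng.randint(1, 3)):
        expr = _random_expr(rng, restricted_atoms, depth=2)
        model.add(
            RestrictedCombinedClass(
                f"C_{k}", "C", expr, score=Decimal(k + 1)
            )
        )
    return model, records, thresholds


def _random_expr(rng, atoms, depth):
    if depth == 0 or rng.random() < 0.4:
        atom = Atom(rng.choice(atoms))
        return Not(atom) if rng.random() < 0.3 else atom
    op = rng.choice((And, Or))
    return op(tuple(_random_expr(rng, atoms, depth - 1) for _ in range(2)))


# ---------------------------------------------------------------------------
# Independent oracle: direct one-shot evaluation
# ---------------------------------------------------------------------------


def oracle_memberships(model, records, thresholds):
    """Expected final memberships, computed directly without the engine."""
    values = {
        name: items[0].value if items else None for name, items in records.items()
    }
    members = set()
    derived_vals = {}
    for name, (kind, spec, t) in thresholds.items():
        if kind == "single":
            v = values.get(spec)
            if v is not None and v >= t:
                members.add(name)
        else:
            a, op, b = spec
            va, vb = values.get(a), values.get(b)
            if va is None or vb is None:
                continue
            result = va + vb if op == "+" else va - vb
            derived_vals[spec] = result
            if result >= t:
                members.add(name)
    for cls in model.restricted_combined_classes():
        if _eval_closed(cls.expression, members):
            members.add(cls.name)
    return members


def _eval_closed(expr, members):
    if isinstance(expr, Atom):
        return expr.name in members
    if isinstance(expr, Not):
        return not _eval_closed(expr.child, members)
    if isinstance(expr, And):
        return all(_eval_closed(c, members) for c in expr.children)
    return any(_eval_closed(c, members) for c in expr.children)
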