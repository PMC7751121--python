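"""Boolean class-membership expressions and mathematical formulas.

Two small languages live here:

* **Boolean expressions** combine restricted phenotype class names with
  ``AND``/``OR``/``NOT`` (case-insensitive) and parentheses. They are
  evaluated under Kleene three-valued logic, because during reasoning a class
  membership may be *unknown* (not yet inferred) rather than false.

* **Formulas** are arithmetic/functional expressions over variables bound to
  phenotype values. A leading dollar sign (``$Name``) binds the *record date*
  of the variable's instance instead of its value, which is how temporal
  relations such as "the first T2DM medication precedes the first T1DM
  medication" are expressed: ``GT($T1DM_Medication, $T2DM_Medication)``.

Built-in functions: ``GT``, ``LT``, ``EQ`` (three-way comparison of decimals
or dates, returning -1/0/1 and -1 when an operand is missing), ``DATEDIFF``
(days), ``ABS``, ``MIN``, ``MAX`` and ``IF``. Additional functions may be
registered via :func:`register_function`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import date as _date
from decimal import Decimal, DivisionByZero, InvalidOperation
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple, Union

from .errors import (
    AggregateError,
    DnfExplosionError,
    ExpressionSyntaxError,
    FormulaEvaluationError,
    MissingAtomError,
)
from .values import AggregateFunction, DataType, PhenotypeValue, Scalar, Trilean

__all__ = [
    "Atom",
    "Not",
    "And",
    "Or",
    "BooleanExpr",
    "parse_boolean",
    "render_boolean",
    "boolean_atoms",
    "evaluate_boolean",
    "Conjunction",
    "to_dnf",
    "Num",
    "Var",
    "BinOp",
    "Func",
    "Formula",
    "parse_formula",
    "render_formula",
    "formula_variables",
    "evaluate_formula",
    "apply_aggregate",
    "register_function",
    "MAX_DNF_CONJUNCTIONS",
]

# ---------------------------------------------------------------------------
# Boolean expression AST
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Atom:
    name: str


@dataclass(frozen=True)
class Not:
    child: "BooleanExpr"


@dataclass(frozen=True)
class And:
    children: Tuple["BooleanExpr", ...]

    def __post_init__(self):
        if len(self.children) < 2:
            raise ExpressionSyntaxError("AND requires at least two operands")


@dataclass(frozen=True)
class Or:
    children: Tuple["BooleanExpr", ...]

    def __post_init__(self):
        if len(self.children) < 2:
            raise ExpressionSyntaxError("OR requires at least two operands")


BooleanExpr = Union[Atom, Not, And, Or]

_IDENT = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")
_BOOL_TOKEN = re.compile(r"\s*(?:(?P<ident>[A-Za-z_][A-Za-z0-9_]*)|(?P<lparen>\()|(?P<rparen>\)))")


def _tokenize_boolean(text: str) -> List[Tuple[str, str, int]]:
    tokens: List[Tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        m = _BOOL_TOKEN.match(text, pos)
        if not m:
            if text[pos:].strip():
                raise ExpressionSyntaxError(f"unexpected character {text[pos]!r}", pos)
            break
        if m.lastgroup == "ident":
            word = m.group("ident")
            kind = word.upper() if word.upper() in ("AND", "OR", "NOT") else "IDENT"
            tokens.append((kind, word, m.start("ident")))
        elif m.lastgroup == "lparen":
            tokens.append(("LPAREN", "(", m.start()))
        else:
            tokens.append(("RPAREN", ")", m.start()))
        pos = m.end()
    return tokens


class _BoolParser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize_boolean(text)
        self.i = 0

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else (None, None, len(self.text))

    def next(self):
        tok = self.peek()
        self.i += 1
        return tok

    def expect(self, kind: str):
        tok = self.next()
        if tok[0] != kind:
            raise ExpressionSyntaxError(f"expected {kind}, found {tok[1]!r}", tok[2])
        return tok

    def parse(self) -> BooleanExpr:
        expr = self.parse_or()
        tok = self.peek()
        if tok[0] is not None:
            raise ExpressionSyntaxError(f"unexpected token {tok[1]!r}", tok[2])
        return expr

    def parse_or(self) -> BooleanExpr:
        parts = [self.parse_and()]
        while self.peek()[0] == "OR":
            self.next()
            parts.append(self.parse_and())
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    def parse_and(self) -> BooleanExpr:
        parts = [self.parse_unary()]
        while self.peek()[0] == "AND":
            self.next()
            parts.append(self.parse_unary())
        return parts[0] if len(parts) == 1 else And(tuple(parts))

    def parse_unary(self) -> BooleanExpr:
        kind, value, pos = self.peek()
        if kind == "NOT":
            self.next()
            return Not(self.parse_unary())
        if kind == "LPAREN":
            self.next()
            expr = self.parse_or()
            self.expect("RPAREN")
            return expr
        if kind == "IDENT":
            self.next()
            return Atom(value)
        raise ExpressionSyntaxError(f"expected class name, NOT or '(', found {value!r}", pos)


def parse_boolean(text: str) -> BooleanExpr:
    """Parse a Boolean class-membership expression.

    AND binds tighter than OR; NOT binds tightest; keywords are
    case-insensitive; atoms are class-name identifiers.
    """
    if not text or not text.strip():
        raise ExpressionSyntaxError("empty expression")
    return _BoolParser(text).parse()


def render_boolean(expr: BooleanExpr) -> str:
    """Render an AST back to text; ``parse_boolean(render_boolean(e)) == e``."""

    def go(e: BooleanExpr, parent: str) -> str:
        if isinstance(e, Atom):
            return e.name
        if isinstance(e, Not):
            return "NOT " + go(e.child, "NOT")
        if isinstance(e, And):
            text = " AND ".join(go(c, "AND") for c in e.children)
            # parens under NOT for precedence, under AND so n-ary nesting
            # survives the round trip instead of flattening
            return f"({text})" if parent in ("NOT", "AND") else text
        text = " OR ".join(go(c, "OR") for c in e.children)
        return f"({text})" if parent in ("NOT", "AND", "OR") else text

    return go(expr, "")


def boolean_atoms(expr: BooleanExpr) -> set:
    """Set of class names referenced by the expression."""
    if isinstance(expr, Atom):
        return {expr.name}
    if isinstance(expr, Not):
        return boolean_atoms(expr.child)
    out: set = set()
    for child in expr.children:
        out |= boolean_atoms(child)
    return out


def evaluate_boolean(expr: BooleanExpr, membership: Mapping[str, Trilean]) -> Trilean:
    """Evaluate under Kleene three-valued logic.

    ``membership`` maps every atom to ``True``, ``False`` or ``None``
    (unknown). AND is true iff all children are true and false if any child
    is false; OR is dual; NOT swaps true/false and preserves unknown.
    """
    if isinstance(expr, Atom):
        if expr.name not in membership:
            raise MissingAtomError(f"no truth value supplied for atom {expr.name!r}")
        return membership[expr.name]
    if isinstance(expr, Not):
        v = evaluate_boolean(expr.child, membership)
        return None if v is None else not v
    values = [evaluate_boolean(c, membership) for c in expr.children]
    if isinstance(expr, And):
        if any(v is False for v in values):
            return False
        return True if all(v is True for v in values) else None
    if any(v is True for v in values):
        return True
    return False if all(v is False for v in values) else None


# ---------------------------------------------------------------------------
# Disjunctive normal form
# ---------------------------------------------------------------------------

#: One conjunction of literals: ordered tuple of (class name, negated flag).
Conjunction = Tuple[Tuple[str, bool], ...]

MAX_DNF_CONJUNCTIONS = 4096


def _nnf(expr: BooleanExpr, negate: bool = False) -> BooleanExpr:
    """Push negations down to atoms (negation normal form)."""
    if isinstance(expr, Atom):
        return Not(expr) if negate else expr
    if isinstance(expr, Not):
        return _nnf(expr.child, not negate)
    children = tuple(_nnf(c, negate) for c in expr.children)
    if isinstance(expr, And):
        return Or(children) if negate else And(children)
    return And(children) if negate else Or(children)


def to_dnf(expr: BooleanExpr, max_conjunctions: int = MAX_DNF_CONJUNCTIONS) -> List[Conjunction]:
    """Convert to disjunctive normal form.

    Returns a deterministically ordered list of conjunctions, each a tuple of
    (atom, negated) literals sorted by atom name. Contradictory conjunctions
    (containing ``A`` and ``NOT A``) are dropped, duplicate conjunctions are
    merged. Raises :class:`DnfExplosionError` if the result would exceed
    ``max_conjunctions``.
    """

    def go(e: BooleanExpr) -> List[Dict[str, bool]]:
        if isinstance(e, Atom):
            return [{e.name: False}]
        if isinstance(e, Not):  # NNF guarantees the child is an atom
            return [{e.child.name: True}]
        if isinstance(e, Or):
            out: List[Dict[str, bool]] = []
            for child in e.children:
                out.extend(go(child))
                if len(out) > max_conjunctions:
                    raise DnfExplosionError(
                        f"DNF exceeds {max_conjunctions} conjunctions"
                    )
            return out
        # And: distribute
        product: List[Dict[str, bool]] = [{}]
        for child in e.children:
            branches = go(child)
            merged: List[Dict[str, bool]] = []
            for left in product:
                for right in branches:
                    conj = dict(left)
                    contradictory = False
                    for name, neg in right.items():
                        if name in conj and conj[name] != neg:
                            contradictory = True
                            break
                        conj[name] = neg
                    if not contradictory:
                        merged.append(conj)
                if len(merged) > max_conjunctions:
                    raise DnfExplosionError(
                        f"DNF exceeds {max_conjunctions} conjunctions"
                    )
            product = merged
        return product

    raw = go(_nnf(expr))
    canonical = {tuple(sorted(conj.items())) for conj in raw}
    return sorted(canonical)


# ---------------------------------------------------------------------------
# Formula AST
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Num:
    value: Decimal


@dataclass(frozen=True)
class Var:
    name: str
    use_date: bool = False  # True when written as $Name


@dataclass(frozen=True)
class BinOp:
    op: str  # one of + - * / ^ < <= > >= = !=
    left: "Formula"
    right: "Formula"


@dataclass(frozen=True)
class Func:
    name: str
    args: Tuple["Formula", ...]


Formula = Union[Num, Var, BinOp, Func]

_FORMULA_TOKEN = re.compile(
    r"\s*(?:(?P<num>\d+(?:\.\d+)?)"
    r"|(?P<var>\$?[A-Za-z_][A-Za-z0-9_]*)"
    r"|(?P<op><=|>=|!=|==|[<>=+\-*/^(),]))"
)


def _tokenize_formula(text: str) -> List[Tuple[str, str, int]]:
    tokens: List[Tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if not m:
            if text[pos:].strip():
                raise ExpressionSyntaxError(f"unexpected character {text[pos]!r}", pos)
            break
        kind = m.lastgroup
        tokens.append((kind, m.group(kind), m.start(kind)))
        pos = m.end()
    return tokens


class _FormulaParser:
    """Precedence-climbing parser: comparison < additive < multiplicative
    < unary minus < power (right-assoc) < atoms."""

    def __init__(self, text: str):
        self.tokens = _tokenize_formula(text)
        self.i = 0
        self.text = text

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else (None, None, len(self.text))

    def next(self):
        tok = self.peek()
        self.i += 1
        return tok

    def expect_op(self, op: str):
        tok = self.next()
        if tok[0] != "op" or tok[1] != op:
            raise ExpressionSyntaxError(f"expected {op!r}, found {tok[1]!r}", tok[2])

    def parse(self) -> Formula:
        expr = self.parse_comparison()
        tok = self.peek()
        if tok[0] is not None:
            raise ExpressionSyntaxError(f"unexpected token {tok[1]!r}", tok[2])
        return expr

    def parse_comparison(self) -> Formula:
        left = self.parse_additive()
        kind, value, _ = self.peek()
        if kind == "op" and value in ("<", "<=", ">", ">=", "=", "==", "!="):
            self.next()
            op = "=" if value == "==" else value
            return BinOp(op, left, self.parse_additive())
        return left

    def parse_additive(self) -> Formula:
        left = self.parse_multiplicative()
        while True:
            kind, value, _ = self.peek()
            if kind == "op" and value in ("+", "-"):
                self.next()
                left = BinOp(value, left, self.parse_multiplicative())
            else:
                return left

    def parse_multiplicative(self) -> Formula:
        left = self.parse_unary()
        while True:
            kind, value, _ = self.peek()
            if kind == "op" and value in ("*", "/"):
                self.next()
                left = BinOp(value, left, self.parse_unary())
            else:
                return left

    def parse_unary(self) -> Formula:
        kind, value, _ = self.peek()
        if kind == "op" and value == "-":
            self.next()
            return BinOp("-", Num(Decimal(0)), self.parse_unary())
        return self.parse_power()

    def parse_power(self) -> Formula:
        base = self.parse_primary()
        kind, value, _ = self.peek()
        if kind == "op" and value == "^":
            self.next()
            return BinOp("^", base, self.parse_unary())  # right-associative
        return base

    def parse_primary(self) -> Formula:
        kind, value, pos = self.next()
        if kind == "num":
            return Num(Decimal(value))
        if kind == "var":
            if not value.startswith("$") and self.peek()[:2] == ("op", "("):
                self.next()
                args: List[Formula] = []
                if self.peek()[:2] != ("op", ")"):
                    args.append(self.parse_comparison())
                    while self.peek()[:2] == ("op", ","):
                        self.next()
                        args.append(self.parse_comparison())
                self.expect_op(")")
                return Func(value.upper(), tuple(args))
            if value.startswith("$"):
                return Var(value[1:], use_date=True)
            return Var(value)
        if kind == "op" and value == "(":
            expr = self.parse_comparison()
            self.expect_op(")")
            return expr
        raise ExpressionSyntaxError(f"unexpected token {value!r}", pos)


def parse_formula(text: str) -> Formula:
    """Parse a formula string into its AST."""
    if not text or not text.strip():
        raise ExpressionSyntaxError("empty formula")
    return _FormulaParser(text).parse()


def render_formula(formula: Formula) -> str:
    """Render an AST to text; round-trips through :func:`parse_formula`."""
    if isinstance(formula, Num):
        return format(formula.value, "f")
    if isinstance(formula, Var):
        return ("$" if formula.use_date else "") + formula.name
    if isinstance(formula, Func):
        return f"{formula.name}({', '.join(render_formula(a) for a in formula.args)})"
    left = render_formula(formula.left)
    right = render_formula(formula.right)
    if not isinstance(formula.left, (Num, Var, Func)):
        left = f"({left})"
    if not isinstance(formula.right, (Num, Var, Func)):
        right = f"({right})"
    return f"{left} {formula.op} {right}"


def formula_variables(formula: Formula) -> set:
    """Names of all variables referenced by the formula (without ``$``)."""
    if isinstance(formula, Var):
        return {formula.name}
    if isinstance(formula, BinOp):
        return formula_variables(formula.left) | formula_variables(formula.right)
    if isinstance(formula, Func):
        out: set = set()
        for arg in formula.args:
            out |= formula_variables(arg)
        return out
    return set()


# ---------------------------------------------------------------------------
# Formula evaluation
# ---------------------------------------------------------------------------


def _three_way(a, b) -> Decimal:
    """-1/0/1 comparison; -1 when either operand is missing."""
    if a is None or b is None:
        return Decimal(-1)
    _check_comparable(a, b)
    if a > b:
        return Decimal(1)
    if a < b:
        return Decimal(-1)
    return Decimal(0)


def _check_comparable(a, b) -> None:
    for x in (a, b):
        if not isinstance(x, (Decimal, _date, str)):
            raise FormulaEvaluationError(f"operand {x!r} is not comparable")
    if isinstance(a, Decimal) != isinstance(b, Decimal) or isinstance(a, _date) != isinstance(b, _date):
        raise FormulaEvaluationError(f"cannot compare {a!r} with {b!r}")


def _fn_gt(a, b):
    return _three_way(a, b)


def _fn_lt(a, b):
    return _three_way(b, a)


def _fn_eq(a, b):
    if a is None or b is None:
        return Decimal(-1)
    _check_comparable(a, b)
    return Decimal(1) if a == b else Decimal(0)


def _fn_datediff(a, b):
    if a is None or b is None:
        return None
    if not isinstance(a, _date) or not isinstance(b, _date):
        raise FormulaEvaluationError("DATEDIFF requires two dates")
    return Decimal((a - b).days)


def _fn_abs(a):
    if a is None:
        return None
    if not isinstance(a, Decimal):
        raise FormulaEvaluationError("ABS requires a decimal")
    return abs(a)


def _fn_min(*args):
    present = [a for a in args if a is not None]
    if not present:
        return None
    _check_all_same_kind(present, "MIN")
    return min(present)


def _fn_max(*args):
    present = [a for a in args if a is not None]
    if not present:
        return None
    _check_all_same_kind(present, "MAX")
    return max(present)


def _check_all_same_kind(values, fn_name):
    kinds = {type(v) for v in values}
    if len(kinds) > 1 or not all(isinstance(v, (Decimal, _date)) for v in values):
        raise FormulaEvaluationError(f"{fn_name} requires decimals or dates of one kind")


def _fn_if(cond, then, otherwise):
    if cond is None:
        return None
    if isinstance(cond, bool):
        truthy = cond
    elif isinstance(cond, Decimal):
        truthy = cond != 0
    else:
        raise FormulaEvaluationError("IF condition must be boolean or decimal")
    return then if truthy else otherwise


_FUNCTIONS: Dict[str, Callable] = {
    "GT": _fn_gt,
    "LT": _fn_lt,
    "EQ": _fn_eq,
    "DATEDIFF": _fn_datediff,
    "ABS": _fn_abs,
    "MIN": _fn_min,
    "MAX": _fn_max,
    "IF": _fn_if,
}


def register_function(name: str, fn: Callable) -> None:
    """Register a custom formula function (name is upper-cased)."""
    _FUNCTIONS[name.upper()] = fn


def _eval_node(node: Formula, bindings: Mapping[str, Optional[PhenotypeValue]]):
    if isinstance(node, Num):
        return node.value
    if isinstance(node, Var):
        if node.name not in bindings:
            raise FormulaEvaluationError(f"unbound variable {node.name!r}")
        bound = bindings[node.name]
        if bound is None:
            return None
        return bound.record_date if node.use_date else bound.value
    if isinstance(node, Func):
        fn = _FUNCTIONS.get(node.name)
        if fn is None:
            raise FormulaEvaluationError(f"unknown function {node.name!r}")
        args = [_eval_node(a, bindings) for a in node.args]
        try:
            return fn(*args)
        except TypeError as exc:
            raise FormulaEvaluationError(f"{node.name}: {exc}") from exc
    # BinOp
    left = _eval_node(node.left, bindings)
    right = _eval_node(node.right, bindings)
    op = node.op
    if op in ("<", "<=", ">", ">=", "=", "!="):
        if left is None or right is None:
            raise FormulaEvaluationError(f"missing operand for comparison {op!r}")
        _check_comparable(left, right)
        return {
            "<": left < right,
            "<=": left <= right,
            ">": left > right,
            ">=": left >= right,
            "=": left == right,
            "!=": left != right,
        }[op]
    if left is None or right is None:
        raise FormulaEvaluationError(f"missing operand for operator {op!r}")
    if not isinstance(left, Decimal) or not isinstance(right, Decimal):
        raise FormulaEvaluationError(f"operator {op!r} requires decimal operands")
    try:
        if op == "+":
            return left + right
        if op == "-":
            return left - right
        if op == "*":
            return left * right
        if op == "/":
            if right == 0:
                raise FormulaEvaluationError("division by zero")
            return left / right
        if op == "^":
            return left ** right
    except (DivisionByZero, InvalidOperation) as exc:
        raise FormulaEvaluationError(str(exc)) from exc
    raise FormulaEvaluationError(f"unknown operator {op!r}")


def evaluate_formula(
    formula: Union[Formula, str],
    bindings: Mapping[str, Optional[PhenotypeValue]],
) -> Optional[Scalar]:
    """Evaluate a formula against variable bindings.

    ``bindings`` maps plain variable names (no ``$``) to a
    :class:`PhenotypeValue` or ``None`` (missing). Missing values are
    tolerated only inside missing-tolerant functions (GT and friends);
    anywhere else they raise :class:`FormulaEvaluationError`.

    Returns the raw result: a Decimal, bool, str, date, or ``None`` when a
    missing-propagating function yields no value.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return _eval_node(formula, bindings)


# ---------------------------------------------------------------------------
# Aggregate functions
# ---------------------------------------------------------------------------


def apply_aggregate(
    fn: AggregateFunction, items: Sequence[PhenotypeValue]
) -> Optional[PhenotypeValue]:
    """Aggregate multiple data items of one single-phenotype class.

    COUNT of an empty list is 0 (a real value — absence is observable);
    every other aggregate of an empty list is missing (``None``). FIRST/LAST
    require record dates on all items and break date ties by source id, then
    by formatted value, so results are deterministic.
    """
    fn = AggregateFunction(fn)
    if fn is AggregateFunction.COUNT:
        return PhenotypeValue.decimal(len(items))
    if not items:
        return None
    if fn in (AggregateFunction.FIRST, AggregateFunction.LAST):
        if any(item.record_date is None for item in items):
            raise AggregateError(f"{fn.value} requires a record date on every item")
        key = lambda it: (it.record_date, it.source_id or "", it.formatted())
        return min(items, key=key) if fn is AggregateFunction.FIRST else max(items, key=key)
    # MIN/MAX over values
    values = [item.value for item in items]
    if not all(isinstance(v, type(values[0])) for v in values):
        raise AggregateError(f"{fn.value} requires items of one datatype")
    if fn is AggregateFunction.MIN:
        return min(items, key=lambda it: it.value)
    return max(items, key=lambda it: it.value)
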