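"""Expression parsing, three-valued evaluation, DNF, formulas, aggregates."""

from datetime import date
from decimal import Decimal
from itertools import product

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenokit.errors import (
    AggregateError,
    DnfExplosionError,
    ExpressionSyntaxError,
    FormulaEvaluationError,
    MissingAtomError,
)
from phenokit.expressions import (
    And,
    Atom,
    Not,
    Or,
    apply_aggregate,
    evaluate_boolean,
    evaluate_formula,
    parse_boolean,
    parse_formula,
    render_boolean,
    render_formula,
    to_dnf,
)
from phenokit.values import AggregateFunction, PhenotypeValue

# ---------------------------------------------------------------------------
# Hypothesis strategies for random Boolean expressions
# ---------------------------------------------------------------------------

ATOMS = [f"A{i}" for i in range(8)]

atoms_st = st.sampled_from(ATOMS).map(Atom)
exprs_st = st.recursive(
    atoms_st,
    lambda inner: st.one_of(
        inner.map(Not),
        st.lists(inner, min_size=2, max_size=3).map(lambda cs: And(tuple(cs))),
        st.lists(inner, min_size=2, max_size=3).map(lambda cs: Or(tuple(cs))),
    ),
    max_leaves=12,
)


def eval_two_valued(expr, env):
    """Independent classical evaluator used as oracle."""
    if isinstance(expr, Atom):
        return env[expr.name]
    if isinstance(expr, Not):
        return not eval_two_valued(expr.child, env)
    if isinstance(expr, And):
        return all(eval_two_valued(c, env) for c in expr.children)
    return any(eval_two_valued(c, env) for c in expr.children)


class TestParseBoolean:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("A AND B", And((Atom("A"), Atom("B")))),
            ("a or b", Or((Atom("a"), Atom("b")))),
            ("NOT A", Not(Atom("A"))),
            ("A AND (B OR C)", And((Atom("A"), Or((Atom("B"), Atom("C")))))),
            # AND binds tighter than OR
            ("A OR B AND C", Or((Atom("A"), And((Atom("B"), Atom("C")))))),
            (
                "Random_Glucose_ABNORMAL OR Fasting_Glucose_ABNORMAL OR HBA1c_ABNORMAL",
                Or((Atom("Random_Glucose_ABNORMAL"), Atom("Fasting_Glucose_ABNORMAL"), Atom("HBA1c_ABNORMAL"))),
            ),
        ],
    )
    def test_parse(self, text, expected):
        assert parse_boolean(text) == expected

    @pytest.mark.parametrize("text", ["A AND (B OR", "", "AND A", "A B", "A AND ()"])
    def test_syntax_errors(self, text):
        with pytest.raises(ExpressionSyntaxError):
            parse_boolean(text)

    @given(exprs_st)
    @settings(max_examples=100, derandomize=True)
    def test_render_parse_round_trip(self, expr):
        assert parse_boolean(render_boolean(expr)) == expr


class TestEvaluateBoolean:
    def test_kleene_truth_combinations(self):
        A, B = Atom("A"), Atom("B")
        assert evaluate_boolean(Or((A, B)), {"A": True, "B": None}) is True
        assert evaluate_boolean(And((A, B)), {"A": True, "B": None}) is None
        assert evaluate_boolean(And((A, B)), {"A": False, "B": None}) is False
        assert evaluate_boolean(Or((A, B)), {"A": False, "B": None}) is None
        assert evaluate_boolean(Not(A), {"A": None}) is None

    def test_abnormal_lab_disjunction(self):
        """One abnormal lab suffices even when others are normal."""
        expr = parse_boolean(
            "Random_Glucose_ABNORMAL OR Fasting_Glucose_ABNORMAL OR HBA1c_ABNORMAL"
        )
        membership = {
            "Random_Glucose_ABNORMAL": False,
            "Fasting_Glucose_ABNORMAL": True,
            "HBA1c_ABNORMAL": False,
        }
        assert evaluate_boolean(expr, membership) is True

    def test_missing_atom_is_an_error(self):
        with pytest.raises(MissingAtomError):
            evaluate_boolean(Atom("A"), {})

    @given(exprs_st, st.data())
    @settings(max_examples=100, derandomize=True)
    def test_two_valued_inputs_agree_with_classical_logic(self, expr, data):
        from phenokit.expressions import boolean_atoms

        names = sorted(boolean_atoms(expr))
        env = {n: data.draw(st.booleans(), label=n) for n in names}
        assert evaluate_boolean(expr, env) is eval_two_valued(expr, env)


class TestToDnf:
    def test_atom_is_its_own_dnf(self):
        assert to_dnf(Atom("A")) == [(("A", False),)]

    def test_distribution(self):
        expr = parse_boolean("A AND (B OR C)")
        assert to_dnf(expr) == [
            (("A", False), ("B", False)),
            (("A", False), ("C", False)),
        ]

    def test_de_morgan(self):
        assert to_dnf(parse_boolean("NOT (A OR B)")) == [(("A", True), ("B", True))]

    def test_contradictions_dropped(self):
        assert to_dnf(parse_boolean("A AND NOT A")) == []

    def test_explosion_guard(self):
        # (A0 OR B0) AND (A1 OR B1) AND ... has 2^n conjunctions
        clauses = [Or((Atom(f"A{i}"), Atom(f"B{i}"))) for i in range(13)]
        with pytest.raises(DnfExplosionError):
            to_dnf(And(tuple(clauses)))

    @given(exprs_st)
    @settings(max_examples=150, derandomize=True)
    def test_equivalence_against_truth_table(self, expr):
        from phenokit.expressions import boolean_atoms

        names = sorted(boolean_atoms(expr))
        conjs = to_dnf(expr)
        for bits in product((False, True), repeat=len(names)):
            env = dict(zip(names, bits))
            expected = eval_two_valued(expr, env)
            got = any(
                all(env[a] is not neg for a, neg in conj) for conj in conjs
            )
            assert got == expected


class TestFormulas:
    def test_bmi_style_arithmetic(self):
        # 80 kg at 2 m: 80 / 2^2 = 20 (power binds tighter than division)
        bindings = {
            "weight": PhenotypeValue.decimal(80, unit="kg"),
            "height": PhenotypeValue.decimal(2, unit="m"),
        }
        assert evaluate_formula("weight / height ^ 2", bindings) == Decimal(20)

    def test_render_parse_round_trip(self):
        for text in (
            "GT($T1DM_Medication, $T2DM_Medication)",
            "weight / height ^ 2",
            "IF(a > 5, 1, 0)",
            "-(a + b) * 2",
        ):
            ast = parse_formula(text)
            assert parse_formula(render_formula(ast)) == ast

    @pytest.mark.parametrize(
        "d1, d2, expected",
        [
            (date(2019, 6, 1), date(2019, 2, 1), 1),   # first later -> 1
            (date(2019, 2, 1), date(2019, 6, 1), -1),  # first earlier -> -1
            (date(2019, 2, 1), date(2019, 2, 1), 0),   # equal -> 0
        ],
    )
    def test_gt_three_way_comparison(self, d1, d2, expected):
        bindings = {
            "a": PhenotypeValue.date(d1),
            "b": PhenotypeValue.date(d2),
        }
        assert evaluate_formula("GT($a, $b)", bindings) == Decimal(expected)

    def test_gt_missing_operand_returns_minus_one(self):
        bindings = {"a": PhenotypeValue.date(date(2019, 6, 1)), "b": None}
        assert evaluate_formula("GT($a, $b)", bindings) == Decimal(-1)
        assert evaluate_formula("GT($b, $a)", bindings) == Decimal(-1)

    def test_lt_eq_mirror_gt_conventions(self):
        a = PhenotypeValue.decimal(3)
        b = PhenotypeValue.decimal(7)
        assert evaluate_formula("LT(a, b)", {"a": a, "b": b}) == Decimal(1)
        assert evaluate_formula("EQ(a, a)", {"a": a}) == Decimal(1)
        assert evaluate_formula("EQ(a, b)", {"a": a, "b": b}) == Decimal(0)
        assert evaluate_formula("EQ(a, b)", {"a": a, "b": None}) == Decimal(-1)

    def test_datediff_if_abs(self):
        bindings = {
            "a": PhenotypeValue.date(date(2019, 6, 1)),
            "b": PhenotypeValue.date(date(2019, 5, 1)),
            "x": PhenotypeValue.decimal(-4),
        }
        assert evaluate_formula("DATEDIFF($a, $b)", bindings) == Decimal(31)
        assert evaluate_formula("ABS(x)", bindings) == Decimal(4)
        assert evaluate_formula("IF(x < 0, 0 - x, x)", bindings) == Decimal(4)

    def test_division_by_zero_and_missing_operand_raise(self):
        with pytest.raises(FormulaEvaluationError):
            evaluate_formula("1 / 0", {})
        with pytest.raises(FormulaEvaluationError):
            evaluate_formula("a + 1", {"a": None})
        with pytest.raises(FormulaEvaluationError):
            evaluate_formula("a + 1", {})  # unbound

    def test_date_only_usable_inside_functions(self):
        bindings = {"a": PhenotypeValue.date(date(2019, 1, 1))}
        with pytest.raises(FormulaEvaluationError):
            evaluate_formula("$a + 1", bindings)

    @given(
        st.lists(st.decimals(min_value=-1000, max_value=1000, places=2), min_size=1, max_size=6)
    )
    @settings(max_examples=50, derandomize=True)
    def test_min_max_agree_with_builtins(self, values):
        bindings = {f"v{i}": PhenotypeValue.decimal(v) for i, v in enumerate(values)}
        args = ", ".join(bindings)
        assert evaluate_formula(f"MIN({args})", bindings) == min(values)
        assert evaluate_formula(f"MAX({args})", bindings) == max(values)


class TestAggregates:
    def _dated(self, value, when, source_id=None):
        return PhenotypeValue.decimal(value, record_date=when, source_id=source_id)

    def test_count_is_length_including_empty(self):
        assert apply_aggregate(AggregateFunction.COUNT, []).value == 0
        items = [self._dated(1, date(2019, 1, 1))]
        assert apply_aggregate(AggregateFunction.COUNT, items).value == 1

    @given(st.integers(min_value=0, max_value=40))
    @settings(max_examples=30, derandomize=True)
    def test_count_equals_length(self, n):
        items = [PhenotypeValue.decimal(i) for i in range(n)]
        assert apply_aggregate(AggregateFunction.COUNT, items).value == n

    def test_empty_aggregates_are_missing(self):
        for fn in (AggregateFunction.FIRST, AggregateFunction.LAST,
                   AggregateFunction.MIN, AggregateFunction.MAX):
            assert apply_aggregate(fn, []) is None

    def test_first_selects_earliest_and_keeps_value_and_date(self):
        items = [
            self._dated(5, date(2019, 6, 1), "b"),
            self._dated(7, date(2019, 2, 1), "a"),
        ]
        first = apply_aggregate(AggregateFunction.FIRST, items)
        assert first.value == 7 and first.record_date == date(2019, 2, 1)
        last = apply_aggregate(AggregateFunction.LAST, items)
        assert last.value == 5

    def test_first_date_ties_break_on_source_id(self):
        items = [
            self._dated(1, date(2019, 1, 1), "z"),
            self._dated(2, date(2019, 1, 1), "a"),
        ]
        assert apply_aggregate(AggregateFunction.FIRST, items).source_id == "a"

    def test_first_requires_dates(self):
        with pytest.raises(AggregateError):
            apply_aggregate(AggregateFunction.FIRST, [PhenotypeValue.decimal(1)])

    def test_min_max(self):
        items = [self._dated("7.1", date(2019, 1, 1)), self._dated("6.4", date(2019, 2, 1))]
        assert apply_aggregate(AggregateFunction.MIN, items).value == Decimal("6.4")
        assert apply_aggregate(AggregateFunction.MAX, items).value == Decimal("7.1")
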