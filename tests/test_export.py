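"""Decision trees, GraphML, report files, fixture model, synthetic bundles."""

import json
import random
from decimal import Decimal

import pytest

from phenokit import (
    PhenotypeModel,
    build_decision_tree,
    build_t2dm_fixture,
    default_scenarios,
    generate_bundle,
    generate_bundles,
    read_graphml,
    read_report_csv,
    reason,
    reason_bundle,
    to_dnf,
    validate_model,
    write_graphml,
    write_report,
)
from phenokit.errors import ModelError
from phenokit.fixtures import CASE_LABELS, SyntheticScenario
from phenokit.model import (
    CombinedPhenotypeClass,
    RestrictedCombinedClass,
    RestrictedSingleClass,
    SinglePhenotypeClass,
    ValueRestriction,
)
from phenokit.model_io import load_model, model_from_dict, model_to_dict, save_model
from phenokit.values import PhenotypeValue


class TestDecisionTree:
    def test_t2dm_tree_has_five_case_leaves(self, t2dm_model):
        tree = build_decision_tree(t2dm_model, "T2DM_Case")
        assert sorted(set(tree.leaves.values())) == sorted(CASE_LABELS)

    def test_leaf_paths_equal_dnf(self, t2dm_model):
        """Every root-to-leaf conjunction is one DNF conjunction of its leaf's
        expression, and all conjunctions appear as paths."""
        tree = build_decision_tree(t2dm_model, "T2DM_Case")
        paths = tree.leaf_paths()
        expected = []
        for sub in t2dm_model.subclasses_of("T2DM_Case"):
            for conj in to_dnf(sub.expression):
                expected.append((sub.name, tuple(sorted(conj))))
        assert sorted(paths) == sorted(expected)

    def test_single_atom_tree(self):
        m = PhenotypeModel(name="m")
        m.add(
            SinglePhenotypeClass(name="A", fhir_resource_type="Observation"),
            RestrictedSingleClass("A_HIGH", "A", ValueRestriction.ge(1)),
            CombinedPhenotypeClass(name="C"),
            RestrictedCombinedClass("C_1", "C", "A_HIGH"),
        )
        tree = build_decision_tree(m, "C")
        # root, one decision node, one leaf
        assert len(tree.nodes) == 3 and len(tree.leaves) == 1
        ((leaf_cls, conj),) = tree.leaf_paths()
        assert leaf_cls == "C_1" and conj == (("A_HIGH", False),)

    def test_shared_leading_atom_shares_node(self):
        m = PhenotypeModel(name="m")
        m.add(
            SinglePhenotypeClass(name="A", fhir_resource_type="Observation"),
            SinglePhenotypeClass(name="B", fhir_resource_type="Observation"),
            SinglePhenotypeClass(name="X", fhir_resource_type="Observation"),
            RestrictedSingleClass("A_H", "A", ValueRestriction.ge(1)),
            RestrictedSingleClass("B_H", "B", ValueRestriction.ge(1)),
            RestrictedSingleClass("X_H", "X", ValueRestriction.ge(1)),
            CombinedPhenotypeClass(name="C"),
            RestrictedCombinedClass("C_1", "C", "A_H AND B_H"),
            RestrictedCombinedClass("C_2", "C", "A_H AND X_H"),
        )
        tree = build_decision_tree(m, "C")
        decision_labels = [label for label, kind in tree.nodes.values() if kind == "decision"]
        assert decision_labels.count("A_H") == 1  # shared prefix node

    def test_requires_restricted_subclasses(self, t2dm_model):
        with pytest.raises(ModelError):
            build_decision_tree(t2dm_model, "Fasting_Glucose")
        m = PhenotypeModel(name="m").add(CombinedPhenotypeClass(name="C"))
        with pytest.raises(ModelError):
            build_decision_tree(m, "C")


class TestGraphML:
    def test_round_trip(self, t2dm_model, tmp_path):
        tree = build_decision_tree(t2dm_model, "T2DM_Case")
        path = tmp_path / "t2dm.graphml"
        write_graphml(tree, path)
        recovered = read_graphml(path)
        assert recovered.nodes == tree.nodes
        assert sorted(recovered.edges) == sorted(tree.edges)
        assert recovered.leaves == tree.leaves

    def test_node_count_is_decisions_plus_leaves_plus_root(self, t2dm_model, tmp_path):
        tree = build_decision_tree(t2dm_model, "T2DM_Case")
        decisions = sum(1 for _, kind in tree.nodes.values() if kind == "decision")
        leaves = sum(1 for _, kind in tree.nodes.values() if kind == "leaf")
        assert leaves == 5
        assert len(tree.nodes) == decisions + leaves + 1


class TestReportFiles:
    def test_csv_round_trip(self, t2dm_model, medication_order_bundle, tmp_path):
        result = reason_bundle(t2dm_model, medication_order_bundle)
        path = tmp_path / "report.csv"
        write_report(result.report_rows, path)
        assert tuple(read_report_csv(path)) == result.report_rows

    def test_empty_rows_write_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_report([], path)
        assert path.read_text().strip() == "Type,Non-restricted,Restricted"

    def test_xlsx_written(self, t2dm_model, medication_order_bundle, tmp_path):
        from openpyxl import load_workbook

        result = reason_bundle(t2dm_model, medication_order_bundle)
        path = tmp_path / "report.xlsx"
        write_report(result.report_rows, path, format="xlsx")
        ws = load_workbook(path).active
        assert [c.value for c in ws[1]] == ["Type", "Non-restricted", "Restricted"]
        assert ws.max_row == len(result.report_rows) + 1


class TestT2dmFixture:
    def test_fixture_is_valid(self, t2dm_model):
        assert validate_model(t2dm_model) == []

    def test_five_case_classes(self, t2dm_model):
        cases = [c.name for c in t2dm_model.subclasses_of("T2DM_Case")]
        assert len(cases) == 5 and set(cases) == set(CASE_LABELS)

    def test_abnormal_lab_is_three_way_disjunction(self, t2dm_model):
        from phenokit.expressions import Or, boolean_atoms

        expr = t2dm_model["Abnormal_Lab_YES"].expression
        assert isinstance(expr, Or)
        assert boolean_atoms(expr) == {
            "Random_Glucose_ABNORMAL",
            "Fasting_Glucose_ABNORMAL",
            "HBA1c_ABNORMAL",
        }

    def test_threshold_boundary_sweep(self, t2dm_model):
        """The minimal abnormal glucose and the minimal physician-diagnosis
        count coincide with the declared cut-offs."""
        from phenokit.model import restriction_satisfied

        glucose = t2dm_model["Fasting_Glucose_ABNORMAL"].restriction
        abnormal = [v for v in range(100, 150) if restriction_satisfied(glucose, Decimal(v))]
        assert min(abnormal) == 125
        physician = t2dm_model["T2DM_Diagnosis_by_Physician_YES"].restriction
        yes = [c for c in range(0, 11) if restriction_satisfied(physician, Decimal(c))]
        assert min(yes) == 2

    def test_model_file_round_trip(self, t2dm_model, tmp_path):
        for suffix in (".json", ".yaml"):
            path = tmp_path / f"t2dm{suffix}"
            save_model(t2dm_model, path)
            recovered = load_model(path)
            assert model_to_dict(recovered) == model_to_dict(t2dm_model)
            assert validate_model(recovered) == []


class TestSyntheticBundles:
    def test_seeded_generation_is_reproducible(self):
        scenario = SyntheticScenario(label="T2DM_Case_1", seed=99)
        a = json.dumps(generate_bundle(scenario), sort_keys=True)
        b = json.dumps(generate_bundle(scenario), sort_keys=True)
        assert a == b

    def test_bundles_use_only_fixture_resource_types(self, t2dm_model):
        allowed = {"Observation", "Condition", "MedicationStatement"}
        for bundle_doc, _ in generate_bundles(default_scenarios(18, seed=5)):
            for entry in bundle_doc["entry"]:
                assert entry["resource"]["resourceType"] in allowed

    def test_generator_reasoner_agreement_200_scenarios(self, t2dm_model):
        """Every generated bundle reasons to exactly its intended case label
        (and non-cases to no case at all), across all five cases and 'none'."""
        scenarios = default_scenarios(204, seed=20240101)
        assert {s.label for s in scenarios} == set(CASE_LABELS) | {"none"}
        for bundle_doc, label in generate_bundles(scenarios):
            result = reason_bundle(t2dm_model, bundle_doc)
            cases = sorted(m for m in result.memberships if m.startswith("T2DM_Case_"))
            expected = [] if label == "none" else [label]
            assert cases == expected, f"label={label} inferred={cases}"

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            generate_bundle(SyntheticScenario(label="T2DM_Case_9", seed=1))
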