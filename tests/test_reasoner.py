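"""Instance building and the classification–calculation fixpoint loop."""

import random
from datetime import date
from decimal import Decimal

import pytest

from phenokit import (
    PhenotypeModel,
    PhenotypeValue,
    classification_step,
    ingest,
    reason,
    reason_bundle,
    report,
)
from phenokit.errors import MultipleItemsError, UnitMismatchError
from phenokit.model_io import model_from_dict, model_to_dict
from randmodels import oracle_memberships, random_model_and_records


def _records(model, bundle):
    from phenokit import records_from_bundle

    return records_from_bundle(model, bundle)


class TestIngest:
    def test_values_attached_per_class(self, t2dm_model, glucose_dx_bundle):
        state = ingest(t2dm_model, _records(t2dm_model, glucose_dx_bundle), "Patient/103")
        assert state.singles["Fasting_Glucose"].value.value == Decimal(130)
        assert state.singles["T2DM_Diagnosis"].value.value == Decimal(1)

    def test_count_classes_instantiated_even_with_no_items(self, t2dm_model):
        state = ingest(t2dm_model, {}, "p")
        assert state.singles["T2DM_Diagnosis"].value.value == Decimal(0)
        assert state.singles["T1DM_Diagnosis"].value.value == Decimal(0)
        # non-aggregated classes without items stay missing
        assert state.singles["Fasting_Glucose"].value is None
        # FIRST over nothing is missing too
        assert state.singles["T2DM_Medication"].value is None

    def test_first_keeps_earliest_date(self, t2dm_model):
        items = [
            PhenotypeValue.boolean(True, record_date=date(2019, 6, 1), source_id="m2"),
            PhenotypeValue.boolean(True, record_date=date(2019, 2, 1), source_id="m1"),
        ]
        state = ingest(t2dm_model, {"T2DM_Medication": items}, "p")
        assert state.singles["T2DM_Medication"].value.record_date == date(2019, 2, 1)

    def test_multiple_items_without_aggregate_is_hard_error(self, t2dm_model):
        items = [PhenotypeValue.decimal(100, unit="mg/dL"), PhenotypeValue.decimal(110, unit="mg/dL")]
        with pytest.raises(MultipleItemsError):
            ingest(t2dm_model, {"Fasting_Glucose": items}, "p")

    def test_unit_mismatch_is_an_error(self, t2dm_model):
        items = [PhenotypeValue.decimal(7, unit="mmol/L")]
        with pytest.raises(UnitMismatchError):
            ingest(t2dm_model, {"Fasting_Glucose": items}, "p")


class TestClassificationStep:
    def test_single_classifications(self, t2dm_model, glucose_dx_bundle):
        state = ingest(t2dm_model, _records(t2dm_model, glucose_dx_bundle), "p")
        state.iterations = 1
        added = classification_step(state)
        assert "Fasting_Glucose_ABNORMAL" in added  # 130 >= 125
        assert "T2DM_Diagnosis_YES" in added  # count 1 > 0
        assert "Abnormal_Lab_YES" in added  # combined, same step

    def test_repeat_call_is_idempotent(self, t2dm_model, glucose_dx_bundle):
        state = ingest(t2dm_model, _records(t2dm_model, glucose_dx_bundle), "p")
        classification_step(state)
        assert classification_step(state) == set()


class TestReason:
    def test_glucose_and_diagnosis_is_case_3_with_no_derived(self, t2dm_model, glucose_dx_bundle):
        """An abnormal fasting glucose plus a T2DM diagnosis, nothing else:
        case 3, and no formula can be calculated."""
        result = reason_bundle(t2dm_model, glucose_dx_bundle)
        assert "Abnormal_Lab_YES" in result.memberships
        assert "T2DM_Case_3" in result.memberships
        assert result.derived_values == {}
        cases = {m for m in result.memberships if m.startswith("T2DM_Case_")}
        assert cases == {"T2DM_Case_3"}

    def test_medication_order_is_case_1_in_two_iterations(self, t2dm_model, medication_order_bundle):
        """Both medications with the T2DM one earlier: the date comparison is
        calculated (value 1), its restricted class and then case 1 are
        inferred — one extra loop iteration."""
        result = reason_bundle(t2dm_model, medication_order_bundle)
        assert result.derived_values["T2DM_precedes_T1DM_Medication"].value == Decimal(1)
        assert "T2DM_precedes_T1DM_Medication_YES" in result.memberships
        cases = {m for m in result.memberships if m.startswith("T2DM_Case_")}
        assert cases == {"T2DM_Case_1"}
        assert result.iterations == 2

    def test_empty_records_infer_only_absence_classes(self, t2dm_model):
        result = reason(t2dm_model, {}, "p")
        # COUNT instances of 0 satisfy the "= 0" classes; nothing else holds
        assert "T1DM_Diagnosis_NO" in result.memberships
        assert "T2DM_Diagnosis_NO" in result.memberships
        assert not any(m.startswith("T2DM_Case_") for m in result.memberships)
        assert result.derived_values == {}

    def test_no_case_membership_for_unremarkable_patient(self, t2dm_model):
        records = {"Fasting_Glucose": [PhenotypeValue.decimal(90, unit="mg/dL")]}
        result = reason(t2dm_model, records, "p")
        assert not any(m.startswith("T2DM_Case_") for m in result.memberships)

    def test_determinism(self, t2dm_model, medication_order_bundle):
        r1 = reason_bundle(t2dm_model, medication_order_bundle)
        r2 = reason_bundle(t2dm_model, medication_order_bundle)
        assert r1.memberships == r2.memberships
        assert r1.report_rows == r2.report_rows
        assert r1.iterations == r2.iterations


class TestReasonerProperties:
    def test_fixpoint_equals_direct_oracle_on_random_models(self):
        """The iterative loop must land exactly where a one-shot topological
        evaluation of the same stratified model lands."""
        for seed in range(60):
            rng = random.Random(seed)
            model, records, thresholds = random_model_and_records(rng)
            result = reason(model, records, subject="p")
            expected = oracle_memberships(model, records, thresholds)
            assert result.memberships == frozenset(expected), f"seed {seed}"

    def test_termination_bound(self):
        for seed in range(40):
            model, records, _ = random_model_and_records(random.Random(seed))
            result = reason(model, records, subject="p")
            n_derived = len(model.derived_classes())
            assert result.iterations <= n_derived + 1

    def test_memberships_independent_of_registry_order(self, t2dm_model, medication_order_bundle):
        """Shuffling class declaration order must not change the outcome."""
        baseline = reason_bundle(t2dm_model, medication_order_bundle).memberships
        doc = model_to_dict(t2dm_model)
        for seed in range(5):
            rng = random.Random(seed)
            shuffled = dict(doc)
            shuffled["classes"] = doc["classes"][:]
            rng.shuffle(shuffled["classes"])
            model = model_from_dict(shuffled)
            assert reason_bundle(model, medication_order_bundle).memberships == baseline

    def test_score_binding_feeds_parent_formula(self):
        """A combined class's score substitutes into a downstream formula,
        forcing a second loop iteration (classification then calculation)."""
        from phenokit.model import (
            CombinedPhenotypeClass,
            DerivedPhenotypeClass,
            FormulaVariable,
            RestrictedCombinedClass,
            RestrictedSingleClass,
            SinglePhenotypeClass,
            ValueRestriction,
        )

        m = PhenotypeModel(name="score-model")
        m.add(
            SinglePhenotypeClass(name="Bilirubin", unit="mg/dL", fhir_resource_type="Observation"),
            RestrictedSingleClass("Bilirubin_VERY_HIGH", "Bilirubin", ValueRestriction.gt(12)),
            CombinedPhenotypeClass(name="Bilirubin_Component"),
            RestrictedCombinedClass(
                "Bilirubin_Component_4", "Bilirubin_Component", "Bilirubin_VERY_HIGH", score=Decimal(4)
            ),
            DerivedPhenotypeClass(
                name="Organ_Score",
                formula="Bilirubin_Component * 10",
                variables=(FormulaVariable("Bilirubin_Component"),),
            ),
        )
        assert not [d for d in __import__("phenokit").validate_model(m)]
        records = {"Bilirubin": [PhenotypeValue.decimal(13, unit="mg/dL")]}
        result = reason(m, records, "p")
        assert result.derived_values["Organ_Score"].value == Decimal(40)
        assert result.iterations == 2


class TestReport:
    def test_case_1_report_structure(self, t2dm_model, medication_order_bundle):
        result = reason_bundle(t2dm_model, medication_order_bundle)
        rows = report(result)
        by_type = {}
        for t, nonrestricted, restricted in rows:
            by_type.setdefault(t, []).append((nonrestricted, restricted))
        # singles carry their input value
        assert ("T2DM_Diagnosis = 1", ("T2DM_Diagnosis_YES",)) in by_type["single"]
        # the derived row carries the calculated value
        assert ("T2DM_precedes_T1DM_Medication = 1", ("T2DM_precedes_T1DM_Medication_YES",)) in by_type["derived"]
        # combined rows list the inferred case
        assert ("T2DM_Case", ("T2DM_Case_1",)) in by_type["combined"]

    def test_column_three_is_exactly_the_memberships(self, t2dm_model, glucose_dx_bundle):
        result = reason_bundle(t2dm_model, glucose_dx_bundle)
        listed = {name for _, _, restricted in result.report_rows for name in restricted}
        assert listed == set(result.memberships)

    def test_empty_result_has_no_rows(self, t2dm_model):
        # an entirely empty model: nothing to report
        result = reason(PhenotypeModel(name="empty"), {}, "p")
        assert result.report_rows == ()
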