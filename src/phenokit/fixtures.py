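"""The T2DM case-selection fixture model and a synthetic bundle generator.

The model implements the PheKB type 2 diabetes mellitus case-selection
algorithm over eight data elements: counts of T1DM/T2DM diagnoses (ICD-9
billing codes), earliest dates of T1DM/T2DM medications (RxNorm codes),
three laboratory values (fasting glucose, random glucose, HbA1c; LOINC
codes) and physician-entered T2DM diagnoses. Five restricted case classes
encode the selection rules; for example, case 1 holds when no T1DM diagnosis
is present but a T2DM diagnosis and both medications are, with the first
T2DM medication preceding the first T1DM medication, and case 3 when an
abnormal lab and a T2DM diagnosis are present without any T1DM diagnosis or
medications. Cases 2, 4 and 5 are reconstructed from the PheKB flowchart
(they are not spelled out in prose anywhere; treat them as this package's
reading of the flowchart).

Thresholds: fasting glucose abnormal at >= 125 mg/dL; random glucose
abnormal at >= 200 mg/dL and HbA1c at >= 6.5 % (PheKB values); a diagnosis
is "YES" when its count is > 0 and "NO" when it equals 0; physician-entered
diagnoses count as "YES" from 2 upwards.

The synthetic generator emits FHIR R4 bundles whose intended case label is
known by construction, for end-to-end generator/reasoner agreement tests.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass
from datetime import date, timedelta
from decimal import Decimal
from typing import Dict, List, Optional, Sequence, Tuple

from .model import (
    Code,
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
from .values import AggregateFunction, DataType

__all__ = [
    "LOINC",
    "ICD9",
    "RXNORM",
    "SNOMED",
    "RESULT_CODE_SYSTEM",
    "build_t2dm_fixture",
    "SyntheticScenario",
    "default_scenarios",
    "generate_bundle",
    "generate_bundles",
    "CASE_LABELS",
]

LOINC = "http://loinc.org"
ICD9 = "http://hl7.org/fhir/sid/icd-9-cm"
RXNORM = "http://www.nlm.nih.gov/research/umls/rxnorm"
SNOMED = "http://snomed.info/sct"
RESULT_CODE_SYSTEM = "https://www.smith.care/phenoman/t2dm_case_selection_algorithm"

CASE_LABELS = (
    "T2DM_Case_1",
    "T2DM_Case_2",
    "T2DM_Case_3",
    "T2DM_Case_4",
    "T2DM_Case_5",
)

# Codes used by the fixture. The diagnosis/medication/lab code sets follow
# the printed queries where available (T2DM ICD-9 250.00/250.02, T2DM
# medications RxNorm 25789/10633, fasting glucose LOINC 1558-6); the rest are
# representative members of the PheKB value sets.
_T2DM_DX_CODES = ("250.00", "250.02")
_T1DM_DX_CODES = ("250.01", "250.03")
_T2DM_MED_CODES = ("25789", "10633")
_T1DM_MED_CODES = ("253182", "139825")
_FASTING_GLUCOSE = "1558-6"
_RANDOM_GLUCOSE = "2345-7"
_HBA1C = "4548-4"
_PHYSICIAN_DX = "44054006"


def build_t2dm_fixture() -> PhenotypeModel:
    """Construct the complete T2DM case-selection phenotype model."""
    m = PhenotypeModel(
        name="T2DM case selection",
        result_code_system=RESULT_CODE_SYSTEM,
    )
    # --- single phenotype classes (one per data element) ---
    m.add(
        SinglePhenotypeClass(
            name="Fasting_Glucose",
            datatype=DataType.DECIMAL,
            unit="mg/dL",
            codes=[Code(LOINC, _FASTING_GLUCOSE)],
            fhir_resource_type="Observation",
            descriptions={"en": "Fasting glucose [Mass/volume] in Serum or Plasma"},
        ),
        SinglePhenotypeClass(
            name="Random_Glucose",
            datatype=DataType.DECIMAL,
            unit="mg/dL",
            codes=[Code(LOINC, _RANDOM_GLUCOSE)],
            fhir_resource_type="Observation",
        ),
        SinglePhenotypeClass(
            name="HBA1c",
            datatype=DataType.DECIMAL,
            unit="%",
            codes=[Code(LOINC, _HBA1C)],
            fhir_resource_type="Observation",
        ),
        SinglePhenotypeClass(
            name="T1DM_Diagnosis",
            datatype=DataType.DECIMAL,
            aggregate=AggregateFunction.COUNT,
            codes=[Code(ICD9, c) for c in _T1DM_DX_CODES],
            fhir_resource_type="Condition",
        ),
        SinglePhenotypeClass(
            name="T2DM_Diagnosis",
            datatype=DataType.DECIMAL,
            aggregate=AggregateFunction.COUNT,
            codes=[Code(ICD9, c) for c in _T2DM_DX_CODES],
            fhir_resource_type="Condition",
        ),
        SinglePhenotypeClass(
            name="T1DM_Medication",
            datatype=DataType.BOOLEAN,
            aggregate=AggregateFunction.FIRST,
            codes=[Code(RXNORM, c) for c in _T1DM_MED_CODES],
            fhir_resource_type="MedicationStatement",
        ),
        SinglePhenotypeClass(
            name="T2DM_Medication",
            datatype=DataType.BOOLEAN,
            aggregate=AggregateFunction.FIRST,
            codes=[Code(RXNORM, c) for c in _T2DM_MED_CODES],
            fhir_resource_type="MedicationStatement",
        ),
        SinglePhenotypeClass(
            name="T2DM_Diagnosis_by_Physician",
            datatype=DataType.DECIMAL,
            aggregate=AggregateFunction.COUNT,
            codes=[Code(SNOMED, _PHYSICIAN_DX)],
            fhir_resource_type="Condition",
        ),
    )
    # --- restricted single classes (value-range / count restrictions) ---
    m.add(
        RestrictedSingleClass(
            "Fasting_Glucose_ABNORMAL", "Fasting_Glucose", ValueRestriction.ge(125)
        ),
        RestrictedSingleClass(
            "Random_Glucose_ABNORMAL", "Random_Glucose", ValueRestriction.ge(200)
        ),
        RestrictedSingleClass("HBA1c_ABNORMAL", "HBA1c", ValueRestriction.ge("6.5")),
        RestrictedSingleClass("T1DM_Diagnosis_YES", "T1DM_Diagnosis", ValueRestriction.gt(0)),
        RestrictedSingleClass("T1DM_Diagnosis_NO", "T1DM_Diagnosis", ValueRestriction.eq(0)),
        RestrictedSingleClass("T2DM_Diagnosis_YES", "T2DM_Diagnosis", ValueRestriction.gt(0)),
        RestrictedSingleClass("T2DM_Diagnosis_NO", "T2DM_Diagnosis", ValueRestriction.eq(0)),
        RestrictedSingleClass("T1DM_Medication_YES", "T1DM_Medication", ValueRestriction.flag()),
        RestrictedSingleClass("T2DM_Medication_YES", "T2DM_Medication", ValueRestriction.flag()),
        RestrictedSingleClass(
            "T2DM_Diagnosis_by_Physician_YES",
            "T2DM_Diagnosis_by_Physician",
            ValueRestriction.ge(2),
        ),
    )
    # --- derived: does the first T2DM medication precede the first T1DM one?
    m.add(
        DerivedPhenotypeClass(
            name="T2DM_precedes_T1DM_Medication",
            formula="GT($T1DM_Medication, $T2DM_Medication)",
            variables=(
                FormulaVariable("T1DM_Medication", required=False, use_date=True),
                FormulaVariable("T2DM_Medication", required=False, use_date=True),
            ),
            datatype=DataType.DECIMAL,
        ),
        RestrictedDerivedClass(
            "T2DM_precedes_T1DM_Medication_YES",
            "T2DM_precedes_T1DM_Medication",
            ValueRestriction.eq(1),
        ),
    )
    # --- combined: abnormal lab ---
    m.add(
        CombinedPhenotypeClass(name="Abnormal_Lab"),
        RestrictedCombinedClass(
            "Abnormal_Lab_YES",
            "Abnormal_Lab",
            "Random_Glucose_ABNORMAL OR Fasting_Glucose_ABNORMAL OR HBA1c_ABNORMAL",
        ),
    )
    # --- combined: the five case classes ---
    m.add(
        CombinedPhenotypeClass(
            name="T2DM_Case",
            codes=[Code(RESULT_CODE_SYSTEM, "t2dm_case_calculated")],
        ),
        RestrictedCombinedClass(
            "T2DM_Case_1",
            "T2DM_Case",
            "T1DM_Diagnosis_NO AND T2DM_Diagnosis_YES AND T1DM_Medication_YES "
            "AND T2DM_Medication_YES AND T2DM_precedes_T1DM_Medication_YES",
            codes=[Code(RESULT_CODE_SYSTEM, "t2dm_case_1")],
        ),
        RestrictedCombinedClass(
            "T2DM_Case_2",
            "T2DM_Case",
            "T1DM_Diagnosis_NO AND T2DM_Diagnosis_YES AND NOT T1DM_Medication_YES "
            "AND T2DM_Medication_YES",
            codes=[Code(RESULT_CODE_SYSTEM, "t2dm_case_2")],
        ),
        RestrictedCombinedClass(
            "T2DM_Case_3",
            "T2DM_Case",
            "T1DM_Diagnosis_NO AND T2DM_Diagnosis_YES AND NOT T1DM_Medication_YES "
            "AND NOT T2DM_Medication_YES AND Abnormal_Lab_YES",
            codes=[Code(RESULT_CODE_SYSTEM, "t2dm_case_3")],
        ),
        RestrictedCombinedClass(
            "T2DM_Case_4",
            "T2DM_Case",
            "T1DM_Diagnosis_NO AND T2DM_Diagnosis_NO AND T2DM_Medication_YES "
            "AND Abnormal_Lab_YES",
            codes=[Code(RESULT_CODE_SYSTEM, "t2dm_case_4")],
        ),
        RestrictedCombinedClass(
            "T2DM_Case_5",
            "T2DM_Case",
            "T1DM_Diagnosis_NO AND T2DM_Diagnosis_YES AND T1DM_Medication_YES "
            "AND NOT T2DM_Medication_YES AND T2DM_Diagnosis_by_Physician_YES",
            codes=[Code(RESULT_CODE_SYSTEM, "t2dm_case_5")],
        ),
    )
    return m


# ---------------------------------------------------------------------------
# FHIR resource builders (R4 JSON)
# ---------------------------------------------------------------------------


def _observation(rid, subject, system, code, value, unit, when: date) -> Dict:
    return {
        "resourceType": "Observation",
        "id": rid,
        "status": "final",
        "code": {"coding": [{"system": system, "code": code}]},
        "subject": {"reference": subject},
        "effectiveDateTime": when.isoformat(),
        "valueQuantity": {"value": float(value), "unit": unit},
    }


def _condition(rid, subject, system, code, when: date) -> Dict:
    return {
        "resourceType": "Condition",
        "id": rid,
        "code": {"coding": [{"system": system, "code": code}]},
        "subject": {"reference": subject},
        "recordedDate": when.isoformat(),
    }


def _medication_statement(rid, subject, system, code, when: date) -> Dict:
    return {
        "resourceType": "MedicationStatement",
        "id": rid,
        "status": "active",
        "code": {"coding": [{"system": system, "code": code}]},
        "subject": {"reference": subject},
        "effectiveDateTime": when.isoformat(),
    }


@dataclass(frozen=True)
class SyntheticScenario:
    """One synthetic patient scenario with a known intended outcome.

    ``label`` is the case class the generated bundle must reason to, or
    ``"none"`` for a non-case. The ``seed`` drives all random choices, so a
    scenario generates byte-identical bundles on every call.
    """

    label: str
    seed: int
    subject: str = "Patient/103"


def default_scenarios(n: int, seed: int = 42) -> List[SyntheticScenario]:
    """``n`` scenarios cycling through the five cases and "none"."""
    rng = random.Random(seed)
    labels = list(CASE_LABELS) + ["none"]
    return [
        SyntheticScenario(
            label=labels[i % len(labels)],
            seed=rng.randrange(2**31),
            subject=f"Patient/{100 + i}",
        )
        for i in range(n)
    ]


def _abnormal_lab(rng: random.Random, builder, subject, base: date) -> List[Dict]:
    """One randomly chosen abnormal laboratory observation."""
    choice = rng.choice(("fasting", "random", "hba1c"))
    when = base + timedelta(days=rng.randrange(30))
    if choice == "fasting":
        return [builder("obs-fg", subject, LOINC, _FASTING_GLUCOSE, rng.randint(125, 400), "mg/dL", when)]
    if choice == "random":
        return [builder("obs-rg", subject, LOINC, _RANDOM_GLUCOSE, rng.randint(200, 500), "mg/dL", when)]
    return [builder("obs-a1c", subject, LOINC, _HBA1C, round(rng.uniform(6.5, 14.0), 1), "%", when)]


def _normal_labs(rng: random.Random, subject, base: date) -> List[Dict]:
    out = []
    if rng.random() < 0.8:
        out.append(_observation("obs-fg", subject, LOINC, _FASTING_GLUCOSE,
                                rng.randint(70, 124), "mg/dL", base + timedelta(days=rng.randrange(30))))
    if rng.random() < 0.5:
        out.append(_observation("obs-a1c", subject, LOINC, _HBA1C,
                                round(rng.uniform(4.0, 6.4), 1), "%", base + timedelta(days=rng.randrange(30))))
    return out


def generate_bundle(scenario: SyntheticScenario) -> Dict:
    """Generate one FHIR R4 bundle realising the scenario's intended label."""
    rng = random.Random(scenario.seed)
    subject = scenario.subject
    base = date(2019, 1, 1) + timedelta(days=rng.randrange(365))
    resources: List[Dict] = []

    def t2dm_dx(count: int):
        for i in range(count):
            resources.append(
                _condition(f"cond-t2dm-{i}", subject, ICD9, rng.choice(_T2DM_DX_CODES),
                           base + timedelta(days=rng.randrange(60)))
            )

    def physician_dx(count: int):
        for i in range(count):
            resources.append(
                _condition(f"cond-phys-{i}", subject, SNOMED, _PHYSICIAN_DX,
                           base + timedelta(days=rng.randrange(60)))
            )

    def medication(kind: str, when: date, idx: int = 0):
        system_codes = _T2DM_MED_CODES if kind == "t2dm" else _T1DM_MED_CODES
        resources.append(
            _medication_statement(f"med-{kind}-{idx}", subject, RXNORM,
                                  rng.choice(system_codes), when)
        )

    label = scenario.label
    if label == "T2DM_Case_1":
        t2dm_dx(rng.randint(1, 3))
        t2dm_first = base + timedelta(days=rng.randrange(100))
        t1dm_later = t2dm_first + timedelta(days=rng.randint(1, 200))
        medication("t2dm", t2dm_first)
        medication("t1dm", t1dm_later)
        resources.extend(_normal_labs(rng, subject, base))
    elif label == "T2DM_Case_2":
        t2dm_dx(rng.randint(1, 3))
        medication("t2dm", base + timedelta(days=rng.randrange(100)))
        resources.extend(_normal_labs(rng, subject, base))
    elif label == "T2DM_Case_3":
        t2dm_dx(rng.randint(1, 2))
        resources.extend(_abnormal_lab(rng, _observation, subject, base))
    elif label == "T2DM_Case_4":
        medication("t2dm", base + timedelta(days=rng.randrange(100)))
        resources.extend(_abnormal_lab(rng, _observation, subject, base))
    elif label == "T2DM_Case_5":
        t2dm_dx(rng.randint(1, 3))
        medication("t1dm", base + timedelta(days=rng.randrange(100)))
        physician_dx(rng.randint(2, 5))
        resources.extend(_normal_labs(rng, subject, base))
    elif label == "none":
        variant = rng.choice(("healthy", "t1dm", "t2dm_dx_only"))
        if variant == "healthy":
            resources.extend(_normal_labs(rng, subject, base))
        elif variant == "t1dm":
            for i in range(rng.randint(1, 3)):
                resources.append(
                    _condition(f"cond-t1dm-{i}", subject, ICD9, rng.choice(_T1DM_DX_CODES),
                               base + timedelta(days=rng.randrange(60)))
                )
            medication("t1dm", base + timedelta(days=rng.randrange(100)))
        else:
            t2dm_dx(rng.randint(1, 2))
            resources.extend(_normal_labs(rng, subject, base))
    else:
        raise ValueError(f"unknown scenario label {scenario.label!r}")

    return {
        "resourceType": "Bundle",
        "type": "collection",
        "entry": [{"resource": r} for r in resources],
    }


def generate_bundles(
    scenarios: Sequence[SyntheticScenario],
) -> List[Tuple[Dict, str]]:
    """Generate (bundle, expected label) pairs for all scenarios."""
    return [(generate_bundle(s), s.label) for s in scenarios]
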