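"""Shared fixtures: the T2DM model and the two canonical patient bundles."""

import pytest

from phenokit import build_t2dm_fixture
from phenokit.fixtures import ICD9, LOINC, RXNORM


def observation(code_system, code, value, unit, when, subject="Patient/103", rid="obs-1"):
    return {
        "resourceType": "Observation",
        "id": rid,
        "status": "final",
        "code": {"coding": [{"system": code_system, "code": code}]},
        "subject": {"reference": subject},
        "effectiveDateTime": when,
        "valueQuantity": {"value": value, "unit": unit},
    }


def condition(code_system, code, when, subject="Patient/103", rid="cond-1"):
    return {
        "resourceType": "Condition",
        "id": rid,
        "code": {"coding": [{"system": code_system, "code": code}]},
        "subject": {"reference": subject},
        "recordedDate": when,
    }


def medication_statement(code, when, subject="Patient/103", rid="med-1"):
    return {
        "resourceType": "MedicationStatement",
        "id": rid,
        "status": "active",
        "code": {"coding": [{"system": RXNORM, "code": code}]},
        "subject": {"reference": subject},
        "effectiveDateTime": when,
    }


def bundle(*resources):
    return {
        "resourceType": "Bundle",
        "type": "collection",
        "entry": [{"resource": r} for r in resources],
    }


@pytest.fixture(scope="session")
def t2dm_model():
    return build_t2dm_fixture()


@pytest.fixture()
def glucose_dx_bundle():
    """Fasting glucose 130 mg/dL plus one T2DM diagnosis — nothing else."""
    return bundle(
        observation(LOINC, "1558-6", 130, "mg/dL", "2019-04-01"),
        condition(ICD9, "250.00", "2019-03-01"),
    )


@pytest.fixture()
def medication_order_bundle():
    """One T2DM diagnosis; T1DM and T2DM medications, T2DM dated earlier."""
    return bundle(
        condition(ICD9, "250.00", "2019-03-01"),
        medication_statement("25789", "2019-02-01", rid="med-t2dm"),
        medication_statement("253182", "2019-06-01", rid="med-t1dm"),
    )
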