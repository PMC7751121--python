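"""Run the T2DM case-selection algorithm on two small patient bundles.

Scenario 1 is a patient with an abnormal fasting glucose (130 mg/dL) and one
T2DM diagnosis: the engine classifies the labs and counts, combines them into
Abnormal_Lab_YES and lands on case 3 without calculating any formula.
Scenario 2 has one T2DM diagnosis plus T1DM and T2DM medications with the
T2DM one dated earlier: the date-comparison formula evaluates to 1, its
restricted class fires and the patient is case 1 — one extra loop iteration.
"""

from phenokit import build_t2dm_fixture, reason_bundle, report


def bundle(*resources):
    return {"resourceType": "Bundle", "type": "collection",
            "entry": [{"resource": r} for r in resources]}


GLUCOSE_130 = {
    "resourceType": "Observation", "id": "obs-1", "status": "final",
    "code": {"coding": [{"system": "http://loinc.org", "code": "1558-6"}]},
    "subject": {"reference": "Patient/103"},
    "effectiveDateTime": "2019-04-01",
    "valueQuantity": {"value": 130, "unit": "mg/dL"},
}
T2DM_DX = {
    "resourceType": "Condition", "id": "cond-1",
    "code": {"coding": [{"system": "http://hl7.org/fhir/sid/icd-9-cm", "code": "250.00"}]},
    "subject": {"reference": "Patient/103"}, "recordedDate": "2019-03-01",
}
T2DM_MED = {
    "resourceType": "MedicationStatement", "id": "med-t2dm", "status": "active",
    "code": {"coding": [{"system": "http://www.nlm.nih.gov/research/umls/rxnorm", "code": "25789"}]},
    "subject": {"reference": "Patient/103"}, "effectiveDateTime": "2019-02-01",
}
T1DM_MED = {
    "resourceType": "MedicationStatement", "id": "med-t1dm", "status": "active",
    "code": {"coding": [{"system": "http://www.nlm.nih.gov/research/umls/rxnorm", "code": "253182"}]},
    "subject": {"reference": "Patient/103"}, "effectiveDateTime": "2019-06-01",
}

model = build_t2dm_fixture()

for title, doc in [
    ("Scenario 1: abnormal glucose + T2DM diagnosis", bundle(GLUCOSE_130, T2DM_DX)),
    ("Scenario 2: T2DM diagnosis + both medications", bundle(T2DM_DX, T2DM_MED, T1DM_MED)),
]:
    result = reason_bundle(model, doc)
    print(f"\n{title}")
    print(f"  loop iterations: {result.iterations}")
    print(f"  inferred case(s): {sorted(m for m in result.memberships if m.startswith('T2DM_Case_'))}")
    print("  reasoner report (Type | Non-restricted | Restricted):")
    for t, nonrestricted, restricted in report(result):
        print(f"    {t:8s} | {nonrestricted:42s} | {'; '.join(restricted)}")
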