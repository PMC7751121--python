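"""Render inferred phenotypes back as FHIR Observation resources.

Inferred combined phenotypes become coded Observations (the non-restricted
class supplies the code, the inferred restricted class the value), ready to
be written back to a FHIR server.
"""

import json

from phenokit import build_t2dm_fixture, reason_bundle, result_to_observation

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

model = build_t2dm_fixture()
bundle = {"resourceType": "Bundle", "type": "collection",
          "entry": [{"resource": GLUCOSE_130}, {"resource": T2DM_DX}]}
result = reason_bundle(model, bundle)

(case,) = [m for m in result.memberships if m.startswith("T2DM_Case_")]
obs = result_to_observation(model, case, "Patient/103")
print(f"inferred case: {case}; resulting Observation resource:")
print(json.dumps(obs, indent=2))
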