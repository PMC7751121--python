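"""Import a data-element catalogue and grow a phenotype model from it.

Metadata repositories describe data elements (name, codes, value domain,
FHIR mapping) before any phenotype logic exists. Importing such a catalogue
materialises one non-restricted single-phenotype class per element; the
modeller then layers restricted classes and expressions on top.
"""

from phenokit import (
    PhenotypeModel,
    RestrictedSingleClass,
    ValueRestriction,
    import_dataset,
    merge_into_model,
    validate_model,
)

CATALOGUE = {
    "dataset": "demo lab elements",
    "elements": [
        {
            "name": "Fasting_Glucose",
            "descriptions": {"en": "Fasting glucose [Mass/volume] in Serum or Plasma"},
            "codes": [{"system": "http://loinc.org", "code": "1558-6"}],
            "datatype": "decimal",
            "unit": "mg/dL",
            "properties": {"FHIR": "Observation"},
        },
        {
            "name": "T2DM_Diagnosis",
            "codes": [{"system": "http://hl7.org/fhir/sid/icd-9-cm", "code": "250.00"}],
            "datatype": "decimal",
            "aggregate": "COUNT",
            "properties": {"FHIR": "Condition"},
        },
    ],
}

classes = import_dataset(CATALOGUE)
print(f"imported {len(classes)} single-phenotype classes:")
for cls in classes:
    print(f"  {cls.name}: {cls.datatype.value}, unit={cls.unit}, "
          f"aggregate={cls.aggregate and cls.aggregate.value}, FHIR={cls.fhir_resource_type}")

model = merge_into_model(PhenotypeModel(name="demo"), classes)
model.add(RestrictedSingleClass("Fasting_Glucose_ABNORMAL", "Fasting_Glucose",
                                ValueRestriction.ge(125)))
print(f"\nmodel now has {len(model.classes)} classes; "
      f"diagnostics: {validate_model(model) or 'none'}")
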