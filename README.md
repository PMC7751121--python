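# phenokit

Computable phenotype algorithms — cohort definitions, clinical scores,
derived measurements — are usually published as prose flowcharts that every
site re-implements by hand. `phenokit` makes them executable: a phenotype
algorithm is written once as a *phenotype model* (a small ontology-style
taxonomy of classes), and an engine computes it for any patient directly
from FHIR R4 JSON resources. It is aimed at clinical-research engineers and
medical informaticians building EHR-driven cohort identification or
automatic phenotype annotation pipelines.

## The model and the reasoning loop

A model contains six kinds of phenotype classes:

| kind | meaning | carries |
|------|---------|---------|
| NSiP | single phenotype (fasting glucose, a diagnosis count) | codes, datatype, unit, aggregate (COUNT/FIRST/LAST/MIN/MAX), FHIR resource type |
| RSiP | restricted single | a value restriction, e.g. `Fasting_Glucose >= 125 mg/dL` |
| NCoP / RCoP | combined phenotype | RCoP: Boolean expression over restricted classes, optional score |
| NDeP / RDeP | derived phenotype | NDeP: formula over other phenotypes, e.g. `GT($T1DM_Medication, $T2DM_Medication)`; RDeP: restriction on the result |

Patient data is ingested into an instance model (`has_value` on single
instances, `has_part` tying them to one composite instance), then the engine
alternates two steps until a fixpoint:

1. **classification** — assign instances to restricted classes: single
   values against their restrictions, the composite instance against RCoP
   Boolean expressions (Kleene three-valued logic: a not-yet-inferred
   membership is *unknown*, not false), derived values against RDeP
   restrictions;
2. **calculation** — evaluate the formula of every derived class whose
   variables are available, creating a new derived instance.

The loop stops when no derived class still awaits calculation; a terminal
closed-world pass then settles `NOT`-atoms and absence-dependent classes.
Each continuing iteration calculates at least one new derived class, so the
loop runs at most `|NDeP| + 1` times. A `$` in a formula variable binds the
record *date* instead of the value, which is how temporal relations
("the first T2DM medication precedes the first T1DM medication") are
expressed; the three-way comparison `GT(a, b)` returns 1/0/−1 and −1 when an
operand is missing.

Around the engine: FHIR Search query and Subscription generation from class
codes and aggregates, extraction of typed values from
Observation/Condition/MedicationStatement resources, rendering of inferred
phenotypes as Observation resources, dataset/metadata import (one NSiP per
data element), model files (JSON/YAML), tabular reasoner reports (CSV/XLSX)
and DNF decision-tree export (GraphML).

## Worked example

The bundled T2DM case-selection model (PheKB-style: five case classes over
eight data elements) run on a patient with one T2DM diagnosis and two
medication statements, the T2DM one dated earlier:

```bash
python examples/reason_t2dm.py
```

```
Scenario 2: T2DM diagnosis + both medications
  loop iterations: 2
  inferred case(s): ['T2DM_Case_1']
  reasoner report (Type | Non-restricted | Restricted):
    single   | T1DM_Diagnosis = 0                         | T1DM_Diagnosis_NO
    single   | T2DM_Diagnosis = 1                         | T2DM_Diagnosis_YES
    single   | T1DM_Medication = true                     | T1DM_Medication_YES
    single   | T2DM_Medication = true                     | T2DM_Medication_YES
    single   | T2DM_Diagnosis_by_Physician = 0            |
    derived  | T2DM_precedes_T1DM_Medication = 1          | T2DM_precedes_T1DM_Medication_YES
    combined | T2DM_Case                                  | T2DM_Case_1
```

Reading the report: the diagnosis counts (0 and 1) put the patient in
`T1DM_Diagnosis_NO` and `T2DM_Diagnosis_YES`; both medications are present,
so the date-comparison formula becomes calculable and yields 1 (first
operand, the T1DM medication date, is later) — that satisfies the
`= 1` restriction, and with it the case-1 expression. The second loop
iteration is exactly the classification round that follows the calculation.

Other examples: `fhir_queries.py` (search/subscription generation),
`decision_tree.py` (GraphML export), `import_metadata.py`,
`synthetic_cohort.py` (seeded bundles with known labels),
`validate_and_save_model.py`, `result_observations.py`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch against the bundled T2DM model: the minimal
fasting-glucose value classified abnormal (integer sweep 0–300), the
aggregated diagnosis count after ingesting one matching Condition, the
three-way date-comparison result for a later first operand, the minimal
physician-diagnosis count classified YES and the unique count satisfying the
diagnosis-absent class (sweeps 0–10), and the case indices the full
reasoning loop infers for the two canonical patient bundles. Results are
written as JSON, one entry per quantity.
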