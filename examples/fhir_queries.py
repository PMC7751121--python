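"""Generate the FHIR Search queries and Subscriptions behind data procurement.

For every single-phenotype class the engine derives a search query from the
class's codes and aggregate function (COUNT maps to _summary=count, FIRST to
a date sort with _count=1), and a Subscription resource whose criteria is the
same query without a subject — the FHIR server then notifies the engine's
endpoint whenever matching resources appear.
"""

import json

from phenokit import build_search_query, build_subscription, build_t2dm_fixture

model = build_t2dm_fixture()

print("Per-class search queries for Patient/103:")
for cls in model.single_classes():
    print(f"  {cls.name}:")
    print(f"    {build_search_query(cls, 'Patient/103').rendered}")

sub = build_subscription(model["Fasting_Glucose"], "https://phenoman.example/t2dm")
print("\nSubscription for Fasting_Glucose (criteria watches all patients):")
print(json.dumps(sub, indent=2))
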