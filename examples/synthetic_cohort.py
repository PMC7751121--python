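"""Generate a synthetic cohort and verify the engine recovers every label.

The generator builds FHIR bundles whose intended case class is known by
construction (values, counts and date orderings are drawn to satisfy exactly
one case, or none). Reasoning over each bundle and comparing against the
intended label is an end-to-end check of extraction, aggregation,
classification and calculation together.
"""

from collections import Counter

from phenokit import build_t2dm_fixture, default_scenarios, generate_bundles, reason_bundle

model = build_t2dm_fixture()
scenarios = default_scenarios(60, seed=42)

agree = 0
by_label = Counter()
for bundle, label in generate_bundles(scenarios):
    result = reason_bundle(model, bundle)
    cases = sorted(m for m in result.memberships if m.startswith("T2DM_Case_"))
    expected = [] if label == "none" else [label]
    agree += cases == expected
    by_label[label] += 1

print(f"scenarios per label: {dict(by_label)}")
print(f"generator/reasoner agreement: {agree}/{len(scenarios)}")
print("(each bundle must reason to exactly its intended case class)")
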