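"""Validate a phenotype model and round-trip it through a model file.

Validation returns diagnostics instead of raising, so a whole specification
can be checked before deployment: unresolved references, datatype-incompatible
restrictions, missing scores and dependency cycles are all reported with the
class name and the rule violated.
"""

from pathlib import Path

from phenokit import (
    CombinedPhenotypeClass,
    RestrictedCombinedClass,
    build_t2dm_fixture,
    load_model,
    save_model,
    validate_model,
)

model = build_t2dm_fixture()
print(f"T2DM fixture: {len(model.classes)} classes, "
      f"diagnostics: {validate_model(model) or 'none (valid)'}")

# break it on purpose: an expression naming an unknown class
model.add(CombinedPhenotypeClass(name="Broken"))
model.add(RestrictedCombinedClass("Broken_YES", "Broken", "No_Such_Class"))
for diagnostic in validate_model(model):
    print(f"  diagnostic: {diagnostic}")

out = Path("scratch") if Path("scratch").is_dir() else Path(".")
path = out / "t2dm_model.json"
save_model(build_t2dm_fixture(), path)
recovered = load_model(path)
print(f"\nsaved and reloaded model file {path}: "
      f"{len(recovered.classes)} classes, diagnostics: {validate_model(recovered) or 'none'}")
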