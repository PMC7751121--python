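"""Import of dataset/metadata specifications (data-element catalogues).

Clinical data elements are typically catalogued in a metadata repository:
each element carries a name, descriptions, terminology associations (codes),
a value domain (datatype, unit) and key–value properties, among them the
FHIR resource type the element is read from. This module materialises one
non-restricted single-phenotype class per element.

The canonical dialect is JSON::

    {
      "dataset": "T2DM data elements",
      "elements": [
        {
          "name": "Fasting_Glucose",
          "descriptions": {"en": "Fasting glucose [Mass/volume] in Serum or Plasma"},
          "codes": [{"system": "http://loinc.org", "code": "1558-6"}],
          "datatype": "decimal",
          "unit": "mg/dL",
          "properties": {"FHIR": "Observation"},
          "aggregate": null
        }
      ]
    }

An XML reader for the same element vocabulary is provided
(``<dataset><element name=...><description lang=...>..</description>
<code system=... code=.../><valueDomain type=... unit=.../>
<property key=... value=.../></element></dataset>``).
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Dict, List, Sequence, Union

from .errors import MetadataImportError, ModelError
from .model import Code, PhenotypeModel, SinglePhenotypeClass
from .values import AggregateFunction, DataType

__all__ = ["import_dataset", "export_dataset", "merge_into_model", "parse_dataset_xml"]


def _element_to_class(element: Dict) -> SinglePhenotypeClass:
    name = element.get("name")
    if not name:
        raise MetadataImportError("data element without a name")
    properties = dict(element.get("properties") or {})
    fhir = properties.get("FHIR")
    if not fhir:
        raise MetadataImportError(f"element {name!r} lacks the required 'FHIR' property")
    try:
        datatype = DataType(element.get("datatype", "decimal"))
    except ValueError as exc:
        raise MetadataImportError(f"element {name!r}: unknown datatype {element.get('datatype')!r}") from exc
    aggregate = element.get("aggregate")
    if aggregate is not None:
        try:
            aggregate = AggregateFunction(aggregate)
        except ValueError as exc:
            raise MetadataImportError(f"element {name!r}: unknown aggregate {aggregate!r}") from exc
    try:
        codes = tuple(Code(**c) for c in element.get("codes", ()))
    except (TypeError, ModelError) as exc:
        raise MetadataImportError(f"element {name!r}: bad terminology association: {exc}") from exc
    annotations = {k: v for k, v in properties.items() if k != "FHIR"}
    return SinglePhenotypeClass(
        name=name,
        datatype=datatype,
        codes=codes,
        unit=element.get("unit"),
        aggregate=aggregate,
        fhir_resource_type=fhir,
        labels=dict(element.get("labels") or {}),
        descriptions=dict(element.get("descriptions") or {}),
        annotations=annotations,
    )


def import_dataset(spec: Union[Dict, str, Path]) -> List[SinglePhenotypeClass]:
    """Materialise one single-phenotype class per data element.

    ``spec`` may be a parsed JSON document, a JSON/XML file path, or raw
    JSON/XML text. Duplicate element names are an error.
    """
    doc = _load(spec)
    classes: List[SinglePhenotypeClass] = []
    seen = set()
    for element in doc.get("elements", []):
        cls = _element_to_class(element)
        if cls.name in seen:
            raise MetadataImportError(f"duplicate data element name {cls.name!r}")
        seen.add(cls.name)
        classes.append(cls)
    return classes


def _load(spec: Union[Dict, str, Path]) -> Dict:
    if isinstance(spec, dict):
        return spec
    if isinstance(spec, Path) or (isinstance(spec, str) and "\n" not in spec and Path(spec).exists()):
        text = Path(spec).read_text()
    else:
        text = str(spec)
    stripped = text.lstrip()
    if stripped.startswith("<"):
        return parse_dataset_xml(text)
    try:
        return json.loads(text)
    except json.JSONDecodeError as exc:
        raise MetadataImportError(f"dataset specification is neither JSON nor XML: {exc}") from exc


def parse_dataset_xml(text: str) -> Dict:
    """Read the XML flavour of the dataset dialect into the JSON shape."""
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise MetadataImportError(f"malformed dataset XML: {exc}") from exc
    elements = []
    for el in root.findall("element"):
        element: Dict = {"name": el.get("name")}
        descriptions = {
            (d.get("lang") or "en"): (d.text or "").strip()
            for d in el.findall("description")
        }
        if descriptions:
            element["descriptions"] = descriptions
        codes = [
            {"system": c.get("system"), "code": c.get("code")}
            for c in el.findall("code")
        ]
        if codes:
            element["codes"] = codes
        domain = el.find("valueDomain")
        if domain is not None:
            element["datatype"] = domain.get("type", "decimal")
            if domain.get("unit"):
                element["unit"] = domain.get("unit")
        if el.get("aggregate"):
            element["aggregate"] = el.get("aggregate")
        element["properties"] = {
            p.get("key"): p.get("value") for p in el.findall("property")
        }
        elements.append(element)
    return {"dataset": root.get("name"), "elements": elements}


def export_dataset(classes: Sequence[SinglePhenotypeClass], dataset: str = "") -> Dict:
    """Inverse of :func:`import_dataset` on the JSON dialect (round-trips)."""
    elements = []
    for cls in classes:
        element: Dict = {
            "name": cls.name,
            "datatype": cls.datatype.value,
            "codes": [{"system": c.system, "code": c.code} for c in cls.codes],
            "properties": {"FHIR": cls.fhir_resource_type, **cls.annotations},
        }
        if cls.unit:
            element["unit"] = cls.unit
        if cls.aggregate:
            element["aggregate"] = cls.aggregate.value
        if cls.labels:
            element["labels"] = dict(cls.labels)
        if cls.descriptions:
            element["descriptions"] = dict(cls.descriptions)
        elements.append(element)
    return {"dataset": dataset, "elements": elements}


def merge_into_model(
    model: PhenotypeModel, classes: Sequence[SinglePhenotypeClass]
) -> PhenotypeModel:
    """Add imported classes to a model.

    Re-importing an identical specification is a no-op; a name collision with
    a *different* definition raises (conflicting redefinitions must be
    resolved by the modeller, not silently merged).
    """
    for cls in classes:
        model.add(cls)
    return model
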