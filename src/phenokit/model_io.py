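"""Declarative model files (JSON or YAML).

A phenotype model can be authored as a plain document instead of through the
API; the schema mirrors the class dataclasses field for field. Boolean
expressions and formulas are stored as their textual form; interval bounds
carry a ``value_type`` discriminator (``decimal`` or ``date``) so exact
decimals and dates survive the round trip.
"""

from __future__ import annotations

import json
from datetime import date as _date
from decimal import Decimal
from pathlib import Path
from typing import Dict, Optional, Union

import yaml

from .errors import ModelError
from .expressions import render_boolean, render_formula
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
from .values import as_date, as_decimal

__all__ = ["model_to_dict", "model_from_dict", "save_model", "load_model"]


def _bound_to_doc(bound) -> Optional[Dict]:
    if bound is None:
        return None
    if isinstance(bound, _date):
        return {"value_type": "date", "value": bound.isoformat()}
    return {"value_type": "decimal", "value": str(bound)}


def _bound_from_doc(doc) -> Union[Decimal, _date, None]:
    if doc is None:
        return None
    if doc["value_type"] == "date":
        return as_date(doc["value"])
    return as_decimal(doc["value"])


def _restriction_to_doc(r: ValueRestriction) -> Dict:
    doc: Dict = {"kind": r.kind}
    if r.kind == "interval":
        doc.update(
            min=_bound_to_doc(r.min),
            max=_bound_to_doc(r.max),
            min_inclusive=r.min_inclusive,
            max_inclusive=r.max_inclusive,
        )
    elif r.kind == "enumeration":
        doc["allowed"] = sorted(str(v) for v in r.allowed)
        doc["allowed_type"] = (
            "decimal" if all(isinstance(v, Decimal) for v in r.allowed) else "string"
        )
    else:
        doc["expected"] = r.expected
    return doc


def _restriction_from_doc(doc: Dict) -> ValueRestriction:
    kind = doc["kind"]
    if kind == "interval":
        return ValueRestriction(
            "interval",
            min=_bound_from_doc(doc.get("min")),
            max=_bound_from_doc(doc.get("max")),
            min_inclusive=doc.get("min_inclusive", True),
            max_inclusive=doc.get("max_inclusive", True),
        )
    if kind == "enumeration":
        values = doc["allowed"]
        if doc.get("allowed_type") == "decimal":
            values = [as_decimal(v) for v in values]
        return ValueRestriction.enumeration(values)
    return ValueRestriction.flag(doc.get("expected", True))


def _codes_to_doc(codes) -> list:
    return [{"system": c.system, "code": c.code} for c in codes]


def model_to_dict(model: PhenotypeModel) -> Dict:
    """Serialise a model to the declarative document shape."""
    classes = []
    for cls in model.classes.values():
        if isinstance(cls, SinglePhenotypeClass):
            doc = {
                "kind": "single",
                "name": cls.name,
                "datatype": cls.datatype.value,
                "codes": _codes_to_doc(cls.codes),
                "unit": cls.unit,
                "aggregate": cls.aggregate.value if cls.aggregate else None,
                "fhir_resource_type": cls.fhir_resource_type,
                "labels": dict(cls.labels),
                "descriptions": dict(cls.descriptions),
                "annotations": dict(cls.annotations),
            }
        elif isinstance(cls, RestrictedSingleClass):
            doc = {
                "kind": "restricted-single",
                "name": cls.name,
                "parent": cls.parent,
                "restriction": _restriction_to_doc(cls.restriction),
                "codes": _codes_to_doc(cls.codes),
            }
        elif isinstance(cls, CombinedPhenotypeClass):
            doc = {
                "kind": "combined",
                "name": cls.name,
                "codes": _codes_to_doc(cls.codes),
            }
        elif isinstance(cls, RestrictedCombinedClass):
            doc = {
                "kind": "restricted-combined",
                "name": cls.name,
                "parent": cls.parent,
                "expression": render_boolean(cls.expression),
                "score": str(cls.score) if cls.score is not None else None,
                "codes": _codes_to_doc(cls.codes),
            }
        elif isinstance(cls, DerivedPhenotypeClass):
            doc = {
                "kind": "derived",
                "name": cls.name,
                "formula": render_formula(cls.formula),
                "variables": [
                    {"name": v.name, "required": v.required, "use_date": v.use_date}
                    for v in cls.variables
                ],
                "datatype": cls.datatype.value,
                "unit": cls.unit,
                "codes": _codes_to_doc(cls.codes),
            }
        elif isinstance(cls, RestrictedDerivedClass):
            doc = {
                "kind": "restricted-derived",
                "name": cls.name,
                "parent": cls.parent,
                "restriction": _restriction_to_doc(cls.restriction),
                "codes": _codes_to_doc(cls.codes),
            }
        else:  # pragma: no cover - exhaustive over class kinds
            raise ModelError(f"cannot serialise {cls!r}")
        classes.append(doc)
    return {
        "name": model.name,
        "result_code_system": model.result_code_system,
        "categories": dict(model.categories),
        "classes": classes,
    }


def model_from_dict(doc: Dict) -> PhenotypeModel:
    """Rebuild a model from its document shape (inverse of model_to_dict)."""
    model = PhenotypeModel(
        name=doc["name"],
        result_code_system=doc.get("result_code_system"),
        categories=dict(doc.get("categories") or {}),
    )
    for cdoc in doc.get("classes", []):
        kind = cdoc.get("kind")
        codes = cdoc.get("codes") or []
        if kind == "single":
            model.add(
                SinglePhenotypeClass(
                    name=cdoc["name"],
                    datatype=cdoc.get("datatype", "decimal"),
                    codes=codes,
                    unit=cdoc.get("unit"),
                    aggregate=cdoc.get("aggregate"),
                    fhir_resource_type=cdoc.get("fhir_resource_type"),
                    labels=dict(cdoc.get("labels") or {}),
                    descriptions=dict(cdoc.get("descriptions") or {}),
                    annotations=dict(cdoc.get("annotations") or {}),
                )
            )
        elif kind == "restricted-single":
            model.add(
                RestrictedSingleClass(
                    cdoc["name"], cdoc["parent"],
                    _restriction_from_doc(cdoc["restriction"]), codes,
                )
            )
        elif kind == "combined":
            model.add(CombinedPhenotypeClass(name=cdoc["name"], codes=codes))
        elif kind == "restricted-combined":
            score = cdoc.get("score")
            model.add(
                RestrictedCombinedClass(
                    cdoc["name"], cdoc["parent"], cdoc["expression"],
                    score=Decimal(score) if score is not None else None,
                    codes=codes,
                )
            )
        elif kind == "derived":
            model.add(
                DerivedPhenotypeClass(
                    name=cdoc["name"],
                    formula=cdoc["formula"],
                    variables=tuple(
                        FormulaVariable(**v) for v in cdoc.get("variables", [])
                    ),
                    datatype=cdoc.get("datatype", "decimal"),
                    unit=cdoc.get("unit"),
                    codes=codes,
                )
            )
        elif kind == "restricted-derived":
            model.add(
                RestrictedDerivedClass(
                    cdoc["name"], cdoc["parent"],
                    _restriction_from_doc(cdoc["restriction"]), codes,
                )
            )
        else:
            raise ModelError(f"unknown class kind {kind!r} in model file")
    return model


def save_model(model: PhenotypeModel, path: Union[str, Path]) -> None:
    """Write a model file; the suffix picks JSON (default) or YAML."""
    path = Path(path)
    doc = model_to_dict(model)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        path.write_text(json.dumps(doc, indent=2))


def load_model(path: Union[str, Path]) -> PhenotypeModel:
    """Read a model file written by :func:`save_model`."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        doc = yaml.safe_load(text)
    else:
        doc = json.loads(text)
    return model_from_dict(doc)
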