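"""FHIR R4 JSON mapping.

Maps single-phenotype classes onto FHIR Search queries and Subscription
resources, extracts typed values out of Observation / Condition /
MedicationStatement resources, and renders inferred phenotypes back as
Observation resources. Resources are plain JSON dicts; only the R4 JSON
dialect is supported.

Conventions (fixed here because the resource types expose several date
attributes): Observation dates come from ``effectiveDateTime``; Condition
dates from ``recordedDate`` with ``onsetDateTime`` as fallback;
MedicationStatement dates from ``effectiveDateTime`` or
``effectivePeriod.start``. The search sort parameter used to realise FIRST /
LAST is ``date`` for Observation, ``recorded-date`` for Condition and
``effective`` for MedicationStatement.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import Decimal
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from .errors import FhirMappingError
from .values import AggregateFunction, DataType, PhenotypeValue, as_date, as_decimal
from .model import (
    Code,
    CombinedPhenotypeClass,
    DerivedPhenotypeClass,
    PhenotypeModel,
    RestrictedCombinedClass,
    RestrictedDerivedClass,
    SinglePhenotypeClass,
)

__all__ = [
    "SearchQuery",
    "parse_search_query",
    "build_search_query",
    "build_subscription",
    "extract_items",
    "bundle_resources",
    "result_to_observation",
    "DATE_SEARCH_PARAM",
    "ENGINE_NAME",
]

ENGINE_NAME = "phenokit"

DATE_SEARCH_PARAM = {
    "Observation": "date",
    "Condition": "recorded-date",
    "MedicationStatement": "effective",
}

_VALUE_PREFIXES = ("gt", "ge", "lt", "le", "eq", "ne")


@dataclass(frozen=True)
class SearchQuery:
    """A FHIR Search query: resource type plus ordered name=value parameters.

    OR-alternatives are comma-joined inside one value; parameters are joined
    by ``&``. Value prefixes (gt/ge/lt/le/eq) only appear on number, date and
    quantity parameters.
    """

    resource_type: str
    parameters: Tuple[Tuple[str, str], ...]

    @property
    def rendered(self) -> str:
        params = "&".join(f"{k}={v}" for k, v in self.parameters)
        return f"{self.resource_type}?{params}"

    def __str__(self) -> str:
        return self.rendered


def parse_search_query(text: str) -> SearchQuery:
    """Parse a rendered query; tolerant of whitespace around separators.

    Accepts both the ``gt75||kg`` quantity form emitted here and the
    double-slash dialect ``gt75//kg`` that appears in print.
    """
    text = text.strip()
    if "?" not in text:
        raise FhirMappingError(f"not a FHIR search query: {text!r}")
    resource_type, _, rest = text.partition("?")
    params: List[Tuple[str, str]] = []
    for part in rest.split("&"):
        if not part.strip():
            continue
        name, sep, value = part.partition("=")
        if not sep:
            raise FhirMappingError(f"malformed parameter {part!r}")
        value = ",".join(v.strip() for v in value.split(","))
        # quantity dialect: gt75//kg -> gt75||kg (never touch scheme '://')
        value = re.sub(r"(?<!:)//", "||", value)
        params.append((name.strip(), value))
    return SearchQuery(resource_type.strip(), tuple(params))


def _render_code(code: Code) -> str:
    return f"{code.system.rstrip('/')}/{code.code}"


def build_search_query(
    nsip: SinglePhenotypeClass, subject: Optional[str] = None
) -> SearchQuery:
    """Build the FHIR Search query that procures data for one NSiP class.

    Codes become a comma-separated OR list on the ``code`` parameter; a
    subject reference is appended when given. The aggregate function maps to
    search machinery: COUNT -> ``_summary=count`` (the server only returns
    the number of matches); FIRST -> sort by the resource's date parameter
    with ``_count=1``; LAST -> the same with a descending sort.
    """
    if not nsip.codes:
        raise FhirMappingError(f"class {nsip.name!r} has no codes to query by")
    if nsip.fhir_resource_type not in DATE_SEARCH_PARAM:
        raise FhirMappingError(f"class {nsip.name!r} has no FHIR resource type")
    params: List[Tuple[str, str]] = [
        ("code", ",".join(_render_code(c) for c in nsip.codes))
    ]
    if subject is not None:
        ref = subject if "/" in subject else f"Patient/{subject}"
        params.append(("subject", ref))
    if nsip.aggregate is AggregateFunction.COUNT:
        params.append(("_summary", "count"))
    elif nsip.aggregate is AggregateFunction.FIRST:
        params.append(("_sort", DATE_SEARCH_PARAM[nsip.fhir_resource_type]))
        params.append(("_count", "1"))
    elif nsip.aggregate is AggregateFunction.LAST:
        params.append(("_sort", "-" + DATE_SEARCH_PARAM[nsip.fhir_resource_type]))
        params.append(("_count", "1"))
    return SearchQuery(nsip.fhir_resource_type, tuple(params))


def build_subscription(nsip: SinglePhenotypeClass, endpoint: str) -> Dict:
    """FHIR Subscription resource notifying ``endpoint`` about new data.

    The criteria is the class's search query without a subject (the
    subscription watches all patients); status, channel type and payload take
    the defaults active / rest-hook / application/json.
    """
    criteria = build_search_query(nsip, subject=None)
    return {
        "resourceType": "Subscription",
        "status": "active",
        "reason": f"data procurement for phenotype class {nsip.name}",
        "criteria": criteria.rendered,
        "channel": {
            "type": "rest-hook",
            "endpoint": endpoint,
            "payload": "application/json",
        },
    }


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------


def bundle_resources(bundle_or_resources: Union[Dict, Sequence[Dict]]) -> List[Dict]:
    """Flatten a Bundle (or pass through a resource list)."""
    if isinstance(bundle_or_resources, dict):
        if bundle_or_resources.get("resourceType") == "Bundle":
            return [
                e["resource"]
                for e in bundle_or_resources.get("entry", [])
                if "resource" in e
            ]
        return [bundle_or_resources]
    return list(bundle_or_resources)


def _codes_match(code_element: Optional[Dict], codes: Sequence[Code]) -> bool:
    if not code_element:
        return False
    wanted = {(c.system.rstrip("/"), c.code) for c in codes}
    for coding in code_element.get("coding", []):
        system = (coding.get("system") or "").rstrip("/")
        if (system, coding.get("code")) in wanted:
            return True
    return False


def _resource_date(resource: Dict):
    rt = resource.get("resourceType")
    raw = None
    if rt == "Observation":
        raw = resource.get("effectiveDateTime")
    elif rt == "Condition":
        raw = resource.get("recordedDate") or resource.get("onsetDateTime")
    elif rt == "MedicationStatement":
        raw = resource.get("effectiveDateTime") or resource.get(
            "effectivePeriod", {}
        ).get("start")
    return as_date(raw) if raw else None


def _observation_value(resource: Dict, nsip: SinglePhenotypeClass):
    if "valueQuantity" in resource:
        q = resource["valueQuantity"]
        return DataType.DECIMAL, as_decimal(q["value"]), q.get("unit") or q.get("code")
    if "valueCodeableConcept" in resource:
        codings = resource["valueCodeableConcept"].get("coding", [])
        if codings:
            return DataType.STRING, codings[0].get("code"), None
        return DataType.STRING, resource["valueCodeableConcept"].get("text"), None
    if "valueString" in resource:
        return DataType.STRING, resource["valueString"], None
    if "valueBoolean" in resource:
        return DataType.BOOLEAN, resource["valueBoolean"], None
    if "valueDateTime" in resource:
        return DataType.DATE, as_date(resource["valueDateTime"]), None
    return None


def extract_items(
    resources: Union[Dict, Sequence[Dict]], nsip: SinglePhenotypeClass
) -> List[PhenotypeValue]:
    """Extract typed, dated values for one NSiP class from FHIR resources.

    Observations contribute their value (quantity -> decimal plus unit,
    codeable concept -> string code); Conditions and MedicationStatements
    contribute presence items (boolean true) — for diagnoses and medications
    only existence and date matter. Resources of the wrong type or whose
    codes do not match the class are skipped.
    """
    items: List[PhenotypeValue] = []
    for resource in bundle_resources(resources):
        if resource.get("resourceType") != nsip.fhir_resource_type:
            continue
        if not _codes_match(resource.get("code"), nsip.codes):
            continue
        record_date = _resource_date(resource)
        source_id = resource.get("id")
        if nsip.fhir_resource_type == "Observation":
            extracted = _observation_value(resource, nsip)
            if extracted is None:
                continue
            datatype, value, unit = extracted
            items.append(
                PhenotypeValue(datatype, value, unit, record_date, source_id)
            )
        else:  # Condition / MedicationStatement: presence
            items.append(
                PhenotypeValue(
                    DataType.BOOLEAN, True, None, record_date, source_id
                )
            )
    return items


# ---------------------------------------------------------------------------
# Result rendering
# ---------------------------------------------------------------------------


def result_to_observation(
    model: PhenotypeModel,
    inferred_name: str,
    subject: str,
    value: Optional[PhenotypeValue] = None,
) -> Dict:
    """Render an inferred combined or derived phenotype as an Observation.

    The ``code`` attribute comes from the *non-restricted* class; the result
    goes into ``valueCodeableConcept`` (coded results: the restricted class's
    own code, e.g. a case identifier) or ``valueQuantity`` (numeric derived
    values or scores). The observation method names this engine.
    """
    cls = model[inferred_name]
    if isinstance(cls, RestrictedCombinedClass):
        parent = model[cls.parent]
        if not parent.codes:
            raise FhirMappingError(f"class {parent.name!r} has no code for the result")
        if cls.codes:
            value_field = {
                "valueCodeableConcept": {
                    "coding": [
                        {"system": cls.codes[0].system, "code": cls.codes[0].code}
                    ]
                }
            }
        elif cls.score is not None:
            value_field = {"valueQuantity": {"value": float(cls.score)}}
        else:
            raise FhirMappingError(
                f"class {cls.name!r} has neither a code nor a score to report"
            )
        code = parent.codes[0]
    elif isinstance(cls, (DerivedPhenotypeClass, RestrictedDerivedClass)):
        ndep = model[cls.parent] if isinstance(cls, RestrictedDerivedClass) else cls
        if not ndep.codes:
            raise FhirMappingError(f"class {ndep.name!r} has no code for the result")
        if value is None or not isinstance(value.value, Decimal):
            raise FhirMappingError("derived results require a calculated decimal value")
        quantity: Dict = {"value": float(value.value)}
        if value.unit or ndep.unit:
            quantity["unit"] = value.unit or ndep.unit
        value_field = {"valueQuantity": quantity}
        code = ndep.codes[0]
    else:
        raise FhirMappingError(
            f"{inferred_name!r} is not an inferred combined or derived phenotype"
        )
    ref = subject if "/" in subject else f"Patient/{subject}"
    return {
        "resourceType": "Observation",
        "status": "final",
        "code": {"coding": [{"system": code.system, "code": code.code}]},
        "subject": {"reference": ref},
        "method": {"text": f"generated by {ENGINE_NAME}"},
        **value_field,
    }
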