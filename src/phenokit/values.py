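"""Typed phenotype values.

The engine supports exactly four primitive data types — decimal, string,
boolean and date — mirroring xsd:decimal/string/boolean/date. Complex source
types (e.g., a FHIR Quantity or code) are mapped onto these primitives: a
quantity becomes a decimal plus a unit string, a code becomes a string.

Decimal values use :class:`decimal.Decimal` throughout so that clinical
cut-offs (e.g., "glucose >= 125 mg/dL") compare exactly, without binary
floating-point fuzz.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date as _date
from datetime import datetime as _datetime
from decimal import Decimal, InvalidOperation
from typing import Optional, Union

from .errors import DataTypeMismatchError

__all__ = [
    "DataType",
    "AggregateFunction",
    "PhenotypeValue",
    "Scalar",
    "Trilean",
    "as_decimal",
    "as_date",
]

#: Three-valued truth: ``True``, ``False`` or ``None`` (unknown).
Trilean = Optional[bool]

Scalar = Union[Decimal, str, bool, _date]


class DataType(str, enum.Enum):
    """The four primitive data types a phenotype value may take."""

    DECIMAL = "decimal"
    STRING = "string"
    BOOLEAN = "boolean"
    DATE = "date"


class AggregateFunction(str, enum.Enum):
    """Aggregations over multiple data items of one single-phenotype class.

    COUNT yields a decimal regardless of item type; FIRST/LAST select the
    earliest/latest item by record date and therefore require dated items.
    """

    COUNT = "COUNT"
    FIRST = "FIRST"
    LAST = "LAST"
    MIN = "MIN"
    MAX = "MAX"


def as_decimal(x: object) -> Decimal:
    """Coerce ``x`` to an exact :class:`~decimal.Decimal`."""
    if isinstance(x, Decimal):
        return x
    if isinstance(x, bool):  # bool is an int subclass; reject explicitly
        raise DataTypeMismatchError(f"cannot treat boolean {x!r} as decimal")
    if isinstance(x, int):
        return Decimal(x)
    if isinstance(x, float):
        return Decimal(str(x))
    if isinstance(x, str):
        try:
            return Decimal(x)
        except InvalidOperation as exc:
            raise DataTypeMismatchError(f"not a decimal: {x!r}") from exc
    raise DataTypeMismatchError(f"not a decimal: {x!r}")


def as_date(x: object) -> _date:
    """Coerce ``x`` to a :class:`datetime.date` (ISO strings accepted)."""
    if isinstance(x, _datetime):
        return x.date()
    if isinstance(x, _date):
        return x
    if isinstance(x, str):
        try:
            return _datetime.fromisoformat(x.replace("Z", "+00:00")).date()
        except ValueError:
            try:
                return _date.fromisoformat(x[:10])
            except ValueError as exc:
                raise DataTypeMismatchError(f"not a date: {x!r}") from exc
    raise DataTypeMismatchError(f"not a date: {x!r}")


_COERCERS = {
    DataType.DECIMAL: as_decimal,
    DataType.DATE: as_date,
}


@dataclass(frozen=True)
class PhenotypeValue:
    """One typed value carried by a phenotype instance (``has_value``).

    Parameters
    ----------
    datatype:
        One of the four primitive data types.
    value:
        The payload; coerced to the canonical Python type for the datatype.
    unit:
        Verbatim unit string; only meaningful on decimals. No unit conversion
        is ever attempted.
    record_date:
        The date the underlying record was made (used by ``$``-bindings and
        the FIRST/LAST aggregates).
    source_id:
        Identifier of the originating resource; used as a deterministic
        tie-break for FIRST/LAST.
    """

    datatype: DataType
    value: Scalar
    unit: Optional[str] = None
    record_date: Optional[_date] = None
    source_id: Optional[str] = None

    def __post_init__(self) -> None:
        dt = DataType(self.datatype)
        object.__setattr__(self, "datatype", dt)
        v = self.value
        if dt is DataType.BOOLEAN:
            if not isinstance(v, bool):
                raise DataTypeMismatchError(f"boolean value expected, got {v!r}")
        elif dt is DataType.STRING:
            if not isinstance(v, str):
                raise DataTypeMismatchError(f"string value expected, got {v!r}")
        else:
            object.__setattr__(self, "value", _COERCERS[dt](v))
        if self.unit is not None and dt is not DataType.DECIMAL:
            raise DataTypeMismatchError("units are only allowed on decimal values")
        if self.record_date is not None:
            object.__setattr__(self, "record_date", as_date(self.record_date))

    # -- convenience constructors -------------------------------------------------

    @classmethod
    def decimal(cls, value, unit=None, record_date=None, source_id=None) -> "PhenotypeValue":
        return cls(DataType.DECIMAL, as_decimal(value), unit, record_date, source_id)

    @classmethod
    def string(cls, value: str, record_date=None, source_id=None) -> "PhenotypeValue":
        return cls(DataType.STRING, value, None, record_date, source_id)

    @classmethod
    def boolean(cls, value: bool, record_date=None, source_id=None) -> "PhenotypeValue":
        return cls(DataType.BOOLEAN, value, None, record_date, source_id)

    @classmethod
    def date(cls, value, record_date=None, source_id=None) -> "PhenotypeValue":
        value = as_date(value)
        return cls(DataType.DATE, value, None, record_date or value, source_id)

    def formatted(self) -> str:
        """Human-readable rendering used in reasoner reports."""
        if self.datatype is DataType.DECIMAL:
            text = format(self.value, "f")
            return f"{text} {self.unit}" if self.unit else text
        if self.datatype is DataType.DATE:
            return self.value.isoformat()
        if self.datatype is DataType.BOOLEAN:
            return "true" if self.value else "false"
        return str(self.value)
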