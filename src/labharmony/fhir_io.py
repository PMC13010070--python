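"""Readers and writers: FHIR R4 Observation JSON and a flat CSV dialect.

An Observation carries the test as a LOINC coding in ``code.coding`` and the
result as ``valueQuantity`` (``value`` plus a coded unit). The harmonization
provenance ledger rides inside the resource itself — the record is its own
audit trail — as one extension holding the ledger JSON, with a second
extension for the status and flags. The extension URLs are fixed constants
below. On read, only codes are trusted; display strings are carried along
but never matched on.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Any, Iterable, Sequence

import pandas as pd

from .engine import HarmonizationResult, LabRecord, ProvenanceEntry
from .knowledge import LOINC_URI, SNOMED_URI, UnitConcept

__all__ = [
    "PROVENANCE_EXTENSION_URL",
    "STATUS_EXTENSION_URL",
    "CSV_COLUMNS",
    "InvalidObservationError",
    "RecordRejected",
    "read_observation",
    "write_observation",
    "read_observations",
    "write_observations",
    "provenance_to_json",
    "provenance_from_json",
    "read_csv_records",
    "write_csv_records",
]

PROVENANCE_EXTENSION_URL = (
    "urn:labharmony:StructureDefinition/harmonization-provenance")
STATUS_EXTENSION_URL = (
    "urn:labharmony:StructureDefinition/harmonization-status")

CSV_COLUMNS = ["record_id", "loinc_code", "loinc_display",
               "unit_code", "unit_display", "value"]
CSV_WRITE_COLUMNS = CSV_COLUMNS + ["unit_system", "status", "flags",
                                   "provenance_json"]


class InvalidObservationError(ValueError):
    """The document is not a well-formed Observation resource."""


class RecordRejected(ValueError):
    """The Observation is valid FHIR but outside scope; carries a reason."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


# ---------------------------------------------------------------------------
# Provenance ledger <-> JSON


def _unit_to_json(unit: UnitConcept | None) -> dict | None:
    if unit is None:
        return None
    return {"code": unit.code, "display": unit.display, "system": unit.system}


def _unit_from_json(obj: dict | None) -> UnitConcept | None:
    if obj is None:
        return None
    return UnitConcept(code=obj["code"], display=obj.get("display", ""),
                       system=obj.get("system", SNOMED_URI))


def _changed_to_json(changed: dict[str, Any]) -> dict[str, Any]:
    return {k: _unit_to_json(v) if isinstance(v, UnitConcept) or
            (k == "unit" and v is None) else v
            for k, v in changed.items()}


def _changed_from_json(changed: dict[str, Any]) -> dict[str, Any]:
    return {k: _unit_from_json(v) if k == "unit" else v
            for k, v in changed.items()}


def provenance_to_json(ledger: Sequence[ProvenanceEntry]) -> list[dict]:
    """Serialize a ledger as the documented array of objects."""
    return [
        {
            "rule": e.rule,
            "description": e.description,
            "changed_fields": _changed_to_json(e.changed_fields),
            "reference_values": e.reference_values,
        }
        for e in ledger
    ]


def provenance_from_json(data: Sequence[dict]) -> list[ProvenanceEntry]:
    return [
        ProvenanceEntry(
            rule=obj["rule"],
            description=obj.get("description", ""),
            changed_fields=_changed_from_json(obj["changed_fields"]),
            reference_values=obj.get("reference_values", {}),
        )
        for obj in data
    ]


# ---------------------------------------------------------------------------
# FHIR Observation


def read_observation(doc: dict, unit_system: str = SNOMED_URI) -> LabRecord:
    """Map one Observation resource to a LabRecord.

    The LOINC code is taken from the ``code.coding`` entry with the LOINC
    system URI; the unit from ``valueQuantity.code``/``system``. A missing
    ``valueQuantity.code`` yields a unit-absent record. Raises
    :class:`InvalidObservationError` for non-Observation resources and
    :class:`RecordRejected` (with a reason) for Observations without a LOINC
    coding or without a numeric value.
    """
    if not isinstance(doc, dict) or doc.get("resourceType") != "Observation":
        raise InvalidObservationError(
            f"expected resourceType 'Observation', got "
            f"{doc.get('resourceType') if isinstance(doc, dict) else type(doc)!r}"
        )
    codings = (doc.get("code") or {}).get("coding") or []
    loinc = next((c for c in codings if c.get("system") == LOINC_URI), None)
    if loinc is None or not loinc.get("code"):
        raise RecordRejected("no_loinc", str(doc.get("id", "")))
    quantity = doc.get("valueQuantity")
    if quantity is None or "value" not in quantity:
        raise RecordRejected("no_numeric_value", str(doc.get("id", "")))
    try:
        value = float(quantity["value"])
    except (TypeError, ValueError):
        raise RecordRejected("non_numeric_value", repr(quantity["value"]))
    if not math.isfinite(value):
        raise RecordRejected("non_numeric_value", repr(quantity["value"]))

    unit = None
    if quantity.get("code"):
        unit = UnitConcept(
            code=str(quantity["code"]),
            display=str(quantity.get("unit", "")),
            system=str(quantity.get("system", "")) or unit_system,
        )

    ledger: list[ProvenanceEntry] = []
    flags: set[str] = set()
    for ext in doc.get("extension") or []:
        if ext.get("url") == PROVENANCE_EXTENSION_URL:
            ledger = provenance_from_json(json.loads(ext["valueString"]))
        elif ext.get("url") == STATUS_EXTENSION_URL:
            payload = json.loads(ext["valueString"])
            flags = set(payload.get("flags", []))

    return LabRecord(
        record_id=str(doc.get("id", "")),
        loinc_code=str(loinc["code"]),
        loinc_display=str(loinc.get("display", "")),
        unit=unit,
        value=value,
        provenance=ledger,
        flags=flags,
    )


def write_observation(result: HarmonizationResult | LabRecord) -> dict:
    """Map a harmonization result (or bare record) to an Observation resource.

    Round-trip safe: :func:`read_observation` on the output reproduces the
    LOINC code, unit, value and ledger exactly. A record with an empty ledger
    and no flags carries no extension array.
    """
    if isinstance(result, HarmonizationResult):
        record, status = result.record, result.status
    else:
        record, status = result, None

    doc: dict[str, Any] = {
        "resourceType": "Observation",
        "id": record.record_id,
        "status": "final",
        "code": {"coding": [{
            "system": LOINC_URI,
            "code": record.loinc_code,
            "display": record.loinc_display,
        }]},
    }
    quantity: dict[str, Any] = {"value": record.value}
    if record.unit is not None:
        quantity["unit"] = record.unit.display
        quantity["system"] = record.unit.system
        quantity["code"] = record.unit.code
    doc["valueQuantity"] = quantity

    extensions = []
    if record.provenance:
        extensions.append({
            "url": PROVENANCE_EXTENSION_URL,
            "valueString": json.dumps(provenance_to_json(record.provenance)),
        })
    if record.flags or status is not None:
        payload: dict[str, Any] = {"flags": sorted(record.flags)}
        if status is not None:
            payload["status"] = status
        extensions.append({
            "url": STATUS_EXTENSION_URL,
            "valueString": json.dumps(payload),
        })
    if extensions:
        doc["extension"] = extensions
    return doc


def read_observations(
    path: str | Path, unit_system: str = SNOMED_URI
) -> tuple[list[LabRecord], list[tuple[str, str]]]:
    """Read a file of Observations (JSON array, single resource, or NDJSON).

    Returns the in-scope records and a list of ``(resource id, reason)`` for
    Observations skipped as out of scope.
    """
    text = Path(path).read_text()
    stripped = text.lstrip()
    if stripped.startswith("["):
        docs = json.loads(text)
    elif stripped.startswith("{") and "\n{" not in text:
        docs = [json.loads(text)]
    else:
        docs = [json.loads(line) for line in text.splitlines() if line.strip()]
    records, skipped = [], []
    for doc in docs:
        try:
            records.append(read_observation(doc, unit_system=unit_system))
        except RecordRejected as exc:
            skipped.append((str(doc.get("id", "")), exc.reason))
    return records, skipped


def write_observations(
    results: Iterable[HarmonizationResult | LabRecord], path: str | Path
) -> None:
    """Write results as a JSON array of Observation resources."""
    docs = [write_observation(r) for r in results]
    Path(path).write_text(json.dumps(docs, indent=2) + "\n")


# ---------------------------------------------------------------------------
# Flat CSV dialect


def read_csv_records(
    path: str | Path, unit_system: str = SNOMED_URI
) -> list[LabRecord]:
    """Read lab records from the flat CSV dialect.

    Required columns: record_id, loinc_code, loinc_display, unit_code,
    unit_display, value. An empty unit_code encodes a missing unit. A
    provenance_json column, when present, restores the ledger.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"CSV {path}: missing mandatory columns {missing}")
    records = []
    for row in df.to_dict("records"):
        unit = None
        if row["unit_code"]:
            unit = UnitConcept(
                code=row["unit_code"],
                display=row.get("unit_display", ""),
                system=row.get("unit_system", "") or unit_system,
            )
        ledger = []
        if row.get("provenance_json"):
            ledger = provenance_from_json(json.loads(row["provenance_json"]))
        flags = set(filter(None, str(row.get("flags", "")).split("|")))
        records.append(LabRecord(
            record_id=row["record_id"],
            loinc_code=row["loinc_code"],
            loinc_display=row.get("loinc_display", ""),
            unit=unit,
            value=float(row["value"]),
            provenance=ledger,
            flags=flags,
        ))
    return records


def write_csv_records(
    results: Sequence[HarmonizationResult | LabRecord], path: str | Path
) -> None:
    """Write results to the flat CSV dialect (round-trips with the reader)."""
    rows = []
    for res in results:
        record = res.record if isinstance(res, HarmonizationResult) else res
        status = res.status if isinstance(res, HarmonizationResult) else ""
        rows.append({
            "record_id": record.record_id,
            "loinc_code": record.loinc_code,
            "loinc_display": record.loinc_display,
            "unit_code": record.unit.code if record.unit else "",
            "unit_display": record.unit.display if record.unit else "",
            "unit_system": record.unit.system if record.unit else "",
            "value": repr(record.value),
            "status": status,
            "flags": "|".join(sorted(record.flags)),
            "provenance_json": (json.dumps(provenance_to_json(record.provenance))
                                if record.provenance else ""),
        })
    pd.DataFrame(rows, columns=CSV_WRITE_COLUMNS).to_csv(path, index=False)
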