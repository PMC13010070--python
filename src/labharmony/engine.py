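"""The two-step harmonization engine.

Rule precedence, applied per record:

1. **Conformance** — if the record's unit code equals the LRR preferred unit
   for its LOINC code, no transformation is attempted (the value may still be
   flagged as out of range).
2. **LOINC conversion** — if the (LOINC, unit) pair keys an LCM row, the
   LOINC code is replaced first.
3. **Unit normalization** — against the (possibly updated) LOINC code's
   preferred unit, every matching UMM row yields a candidate
   ``value' = value * multiplier + scalar``.
4. **Range validation** — a chain is accepted only when its end-state value
   falls within the target LOINC code's reasonable range.
5. **Conflict resolution** — among surviving candidates, the one whose
   transformed value is closest to the target distribution's median wins
   (closest to the mean when the median is 0).

Every accepted transformation appends a provenance entry recording the rule,
a human-readable description, the changed fields with their pre-adjustment
values, and the reference values used — making every harmonization exactly
reversible via :func:`revert`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Sequence

from .knowledge import KnowledgeBase, LRREntry, UMMEntry, UnitConcept

__all__ = [
    "STATUS_CONFORMANT",
    "STATUS_TRANSFORMED",
    "STATUS_UNRESOLVED",
    "STATUS_OUT_OF_RANGE",
    "STATUSES",
    "RULE_LOINC_CONVERSION",
    "LabRecord",
    "ProvenanceEntry",
    "HarmonizationResult",
    "UnknownLoincError",
    "LedgerError",
    "conforms",
    "in_range",
    "apply_lcm",
    "candidate_unit_transforms",
    "resolve_conflict",
    "harmonize_record",
    "harmonize_stream",
    "revert",
]

STATUS_CONFORMANT = "conformant"
STATUS_TRANSFORMED = "transformed"
STATUS_UNRESOLVED = "unresolved"
STATUS_OUT_OF_RANGE = "out_of_range_flagged"
STATUSES = (STATUS_CONFORMANT, STATUS_TRANSFORMED,
            STATUS_UNRESOLVED, STATUS_OUT_OF_RANGE)

RULE_LOINC_CONVERSION = "loinc_conversion"

FLAG_UNKNOWN_LOINC = "unknown_loinc"
FLAG_OUT_OF_RANGE = "out_of_range"
FLAG_UNRESOLVED = "unresolved"

#: Deterministic tiebreak on exact distance ties: value-preserving transforms
#: are preferred over scaling ones.
_TYPE_PRIORITY = {"nullfill": 0, "synonym": 1, "unit_typo": 2, "unit_conversion": 3}


class UnknownLoincError(KeyError):
    """The record's LOINC code has no LRR entry."""


class LedgerError(Exception):
    """A provenance ledger names a field the record does not carry."""


@dataclass
class ProvenanceEntry:
    """One reversible transformation step.

    ``changed_fields`` maps LabRecord attribute names to their pre-adjustment
    values (verbatim objects); replaying them in reverse ledger order restores
    the prior record exactly. ``reference_values`` records what justified the
    adjustment (multiplier, scalar, target range, median/mean used).
    """

    rule: str
    description: str
    changed_fields: dict[str, Any]
    reference_values: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.changed_fields:
            raise ValueError("changed_fields must be non-empty")


@dataclass
class LabRecord:
    """One quantitative laboratory observation.

    Only numeric results are in scope; ``value`` must be finite. ``unit`` is
    optional — an absent unit is itself a correctable error pattern.
    ``provenance`` is append-only and records every engine transformation.
    """

    record_id: str
    loinc_code: str
    loinc_display: str = ""
    unit: UnitConcept | None = None
    value: float = 0.0
    provenance: list[ProvenanceEntry] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.value = float(self.value)
        if not math.isfinite(self.value):
            raise ValueError(f"record {self.record_id}: value must be finite")

    def copy(self) -> "LabRecord":
        return replace(self, provenance=list(self.provenance),
                       flags=set(self.flags))


@dataclass
class HarmonizationResult:
    """Outcome of harmonizing one record."""

    record: LabRecord
    status: str
    applied_rules: list[str] = field(default_factory=list)


def conforms(record: LabRecord, kb: KnowledgeBase) -> bool:
    """True iff the record's unit code equals the LRR preferred unit code.

    Raises :class:`UnknownLoincError` when the LOINC code has no LRR entry;
    :func:`harmonize_record` turns that signal into a flagged pass-through.
    """
    lrr = kb.lrr.get(record.loinc_code)
    if lrr is None:
        raise UnknownLoincError(record.loinc_code)
    return record.unit is not None and record.unit.code == lrr.unit.code


def in_range(value: float, lrr: LRREntry) -> bool:
    """Inclusive plausibility check against the reasonable range."""
    return lrr.min_reasonable <= value <= lrr.max_reasonable


def apply_lcm(record: LabRecord, kb: KnowledgeBase) -> LabRecord | None:
    """Replace the LOINC code when the unit suggests a better one.

    Returns a copy with the new LOINC code and a ``loinc_conversion``
    provenance entry, or ``None`` when no LCM row keys the record's
    (LOINC, unit) pair. Value and unit are untouched.
    """
    if record.unit is None:
        return None
    entry = kb.lcm.get((record.loinc_code, record.unit.code))
    if entry is None:
        return None
    out = record.copy()
    out.provenance.append(ProvenanceEntry(
        rule=RULE_LOINC_CONVERSION,
        description=(
            f"LOINC code changed from {record.loinc_code} to "
            f"{entry.new_loinc_code} because unit "
            f"{record.unit.display or record.unit.code} is incompatible "
            f"with {record.loinc_code}"
        ),
        changed_fields={
            "loinc_code": record.loinc_code,
            "loinc_display": record.loinc_display,
        },
        reference_values={"unit_code": record.unit.code,
                          "new_loinc_code": entry.new_loinc_code},
    ))
    out.loinc_code = entry.new_loinc_code
    out.loinc_display = entry.new_loinc_display
    return out


def candidate_unit_transforms(
    record: LabRecord, kb: KnowledgeBase
) -> list[tuple[UMMEntry, float]]:
    """All UMM rows applicable to the record, with their transformed values.

    A row applies when its incorrect unit matches the record's unit (or is the
    null-unit row when the unit is absent) and its correct unit is the LRR
    preferred unit for the record's LOINC code. The returned values are *not*
    yet range-filtered.
    """
    lrr = kb.lrr.get(record.loinc_code)
    if lrr is None:
        raise UnknownLoincError(record.loinc_code)
    unit_code = record.unit.code if record.unit else None
    out = []
    for entry in kb.umm_for_unit(unit_code):
        if entry.correct_unit.code == lrr.unit.code:
            out.append((entry, entry.transform(record.value)))
    return out


def resolve_conflict(
    candidates: Sequence[tuple[UMMEntry, float]], lrr: LRREntry
) -> tuple[UMMEntry, float]:
    """Pick among range-valid candidates by proximity to the target median.

    When the target distribution's median is 0, distance from the mean is used
    instead. Exact distance ties fall back to a fixed multiplier-type priority
    (nullfill > synonym > unit_typo > unit_conversion), preferring
    value-preserving transforms.
    """
    if not candidates:
        raise ValueError("resolve_conflict requires at least one candidate")
    if len(candidates) == 1:
        return candidates[0]
    anchor = lrr.median if lrr.median != 0 else lrr.mean
    return min(
        candidates,
        key=lambda c: (abs(c[1] - anchor), _TYPE_PRIORITY[c[0].multiplier_type]),
    )


def _umm_provenance(record: LabRecord, entry: UMMEntry, new_value: float,
                    lrr: LRREntry, n_candidates: int) -> ProvenanceEntry:
    old_unit = record.unit
    changed: dict[str, Any] = {"unit": old_unit}
    if new_value != record.value:
        changed["value"] = record.value
    old_label = old_unit.display or old_unit.code if old_unit else "<absent>"
    if entry.multiplier_type == "nullfill":
        desc = (f"absent unit filled with preferred unit "
                f"{lrr.unit.display or lrr.unit.code}")
    elif entry.multiplier_type == "synonym":
        desc = (f"unit {old_label} normalized to synonymous preferred unit "
                f"{lrr.unit.display or lrr.unit.code}")
    elif entry.multiplier_type == "unit_typo":
        desc = (f"unit {old_label} corrected to "
                f"{lrr.unit.display or lrr.unit.code} (known unit error; "
                f"value already on the correct scale)")
    else:
        desc = (f"value converted from {old_label} to "
                f"{lrr.unit.display or lrr.unit.code} "
                f"(x {entry.multiplier:g}"
                + (f" + {entry.scalar_constant:g}" if entry.scalar_constant else "")
                + ")")
    return ProvenanceEntry(
        rule=entry.multiplier_type,
        description=desc,
        changed_fields=changed,
        reference_values={
            "multiplier": entry.multiplier,
            "scalar_constant": entry.scalar_constant,
            "target_range": [lrr.min_reasonable, lrr.max_reasonable],
            "target_median": lrr.median,
            "target_mean": lrr.mean,
            "n_candidates": n_candidates,
        },
    )


def _complete_chain(
    base: LabRecord, kb: KnowledgeBase
) -> tuple[LabRecord, list[str]] | None:
    """Finish a chain on ``base``'s current LOINC code: conform or normalize.

    Returns the transformed record and the rules applied on this leg, or
    ``None`` when no range-valid end state exists.
    """
    lrr = kb.lrr.get(base.loinc_code)
    if lrr is None:
        return None
    if base.unit is not None and base.unit.code == lrr.unit.code:
        # already in the preferred unit; accept only if the value is plausible
        return (base, []) if in_range(base.value, lrr) else None
    candidates = [
        (entry, value)
        for entry, value in candidate_unit_transforms(base, kb)
        if in_range(value, lrr)
    ]
    if not candidates:
        return None
    entry, new_value = resolve_conflict(candidates, lrr)
    out = base.copy()
    out.provenance.append(
        _umm_provenance(base, entry, new_value, lrr, len(candidates)))
    out.unit = lrr.unit
    out.value = new_value
    return out, [entry.multiplier_type]


def harmonize_record(record: LabRecord, kb: KnowledgeBase) -> HarmonizationResult:
    """Harmonize one record; never raises on data problems.

    Outcomes: ``conformant`` (untouched), ``out_of_range_flagged`` (conforming
    unit but implausible value; untouched, flagged), ``transformed`` (a
    range-valid chain of LOINC conversion and/or unit normalization was
    applied), or ``unresolved`` (no valid chain; untouched, flagged). A LOINC
    code absent from the LRR table passes through with flag ``unknown_loinc``.
    """
    lrr = kb.lrr.get(record.loinc_code)
    if lrr is None:
        out = record.copy()
        out.flags.add(FLAG_UNKNOWN_LOINC)
        return HarmonizationResult(record=out, status=STATUS_UNRESOLVED)

    if record.unit is not None and record.unit.code == lrr.unit.code:
        if in_range(record.value, lrr):
            return HarmonizationResult(record=record.copy(),
                                       status=STATUS_CONFORMANT)
        out = record.copy()
        out.flags.add(FLAG_OUT_OF_RANGE)
        return HarmonizationResult(record=out, status=STATUS_OUT_OF_RANGE)

    # LOINC conversion takes precedence; accept it only if the completed
    # chain (conversion plus any unit normalization) ends in range.
    converted = apply_lcm(record, kb)
    if converted is not None:
        finished = _complete_chain(converted, kb)
        if finished is not None:
            rec, rules = finished
            return HarmonizationResult(
                record=rec, status=STATUS_TRANSFORMED,
                applied_rules=[RULE_LOINC_CONVERSION] + rules,
            )

    finished = _complete_chain(record.copy(), kb)
    if finished is not None and finished[1]:
        rec, rules = finished
        return HarmonizationResult(record=rec, status=STATUS_TRANSFORMED,
                                   applied_rules=rules)

    out = record.copy()
    out.flags.add(FLAG_UNRESOLVED)
    return HarmonizationResult(record=out, status=STATUS_UNRESOLVED)


def harmonize_stream(
    records: Iterable[LabRecord], kb: KnowledgeBase
) -> tuple[list[HarmonizationResult], dict[str, int]]:
    """Harmonize a sequence of records, order-preserving.

    Returns the per-record results and a summary count by status. Individual
    data problems become per-record flags; the stream never aborts.
    """
    results = [harmonize_record(r, kb) for r in records]
    counts = {status: 0 for status in STATUSES}
    for res in results:
        counts[res.status] += 1
    return results, counts


def revert(record: LabRecord) -> LabRecord:
    """Undo every ledgered transformation, restoring the original record.

    Pre-adjustment values are replayed in reverse ledger order; an empty
    ledger is the identity. Raises :class:`LedgerError` when an entry names a
    field the record does not carry.
    """
    out = record.copy()
    for entry in reversed(out.provenance):
        for field_name, pre_value in entry.changed_fields.items():
            if not hasattr(out, field_name):
                raise LedgerError(
                    f"ledger names unknown field {field_name!r} "
                    f"on record {record.record_id}"
                )
            setattr(out, field_name, pre_value)
    out.provenance = []
    return out
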