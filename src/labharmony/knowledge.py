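"""Knowledge tables driving the harmonization engine.

Three manually curated tables control every correction the engine makes:

* **LCM** (LOINC conversion map) — maps an incongruous (LOINC, unit) pair to
  a replacement LOINC code that is compatible with the observed unit.
* **LRR** (laboratory reasonable range map) — per LOINC code: the preferred
  unit, a plausibility range ``[min_reasonable, max_reasonable]``, and the
  median/mean of the known-correct value distribution in that unit.
* **UMM** (unit multiplier map) — relates a wrong, synonymous, or absent unit
  to a preferred unit with a multiplicative factor, an additive scalar
  (used only for temperature conversions) and a relationship type.

This module provides the domain types, CSV loaders/writers with integrity
validation, and the empirical derivation of LRR entries from a record corpus
(highest-frequency unit, 0.005/0.995 quantile range).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SNOMED_URI",
    "UCUM_URI",
    "LOINC_URI",
    "QUANTILE_PROBS",
    "MULTIPLIER_TYPES",
    "UnitConcept",
    "LCMEntry",
    "LRREntry",
    "UMMEntry",
    "KnowledgeBase",
    "KnowledgeTableError",
    "IntegrityError",
    "ReferentialError",
    "TableParseError",
    "InsufficientDataError",
    "UnitTieError",
    "build_knowledge_base",
    "load_knowledge_base",
    "write_knowledge_base",
    "empirical_quantiles",
    "derive_lrr_entry",
]

SNOMED_URI = "http://snomed.info/sct"
UCUM_URI = "http://unitsofmeasure.org"
LOINC_URI = "http://loinc.org"

#: Probabilities at which the empirical value distribution is summarized when
#: deriving a reasonable range; the outermost pair becomes [min, max].
QUANTILE_PROBS = (0.005, 0.025, 0.16, 0.5, 0.84, 0.975, 0.995)

MULTIPLIER_TYPES = ("nullfill", "synonym", "unit_conversion", "unit_typo")

LCM_COLUMNS = [
    "old_loinc_code", "old_loinc_display", "old_loinc_system",
    "unit_code", "unit_display", "unit_system",
    "new_loinc_code", "new_loinc_display", "new_loinc_system",
]
LRR_COLUMNS = [
    "loinc_code", "loinc_name", "unit_code", "unit_name",
    "min_reasonable", "max_reasonable", "mean", "median",
]
UMM_COLUMNS = [
    "incorrect_unit_code", "incorrect_unit_name",
    "correct_unit_code", "correct_unit_name",
    "multiplier", "scalar_constant", "multiplier_type",
]


class KnowledgeTableError(Exception):
    """Base class for knowledge-table problems."""


class IntegrityError(KnowledgeTableError):
    """A table violates one of its structural invariants."""


class ReferentialError(IntegrityError):
    """A cross-table reference points at a missing entry."""


class TableParseError(KnowledgeTableError):
    """A CSV cell could not be parsed; carries the offending row number."""


class InsufficientDataError(KnowledgeTableError):
    """Not enough finite values to summarize a distribution."""


class UnitTieError(KnowledgeTableError):
    """Two or more units are tied for highest frequency; no tiebreak is defined."""

    def __init__(self, tied_units: Sequence[str]):
        self.tied_units = sorted(tied_units)
        super().__init__(
            "unit frequency tie between: " + ", ".join(self.tied_units)
        )


@dataclass(frozen=True)
class UnitConcept:
    """A coded unit of measure.

    ``code`` is a concept identifier (SNOMED CT by default); ``system`` may be
    swapped for the UCUM URI without any engine change — the engine matches on
    codes only.
    """

    code: str
    display: str = ""
    system: str = SNOMED_URI

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("unit code must be non-empty")


@dataclass(frozen=True)
class LCMEntry:
    """One LOINC conversion rule, keyed by (old_loinc_code, unit_code)."""

    old_loinc_code: str
    old_loinc_display: str
    old_loinc_system: str
    unit_code: str
    unit_display: str
    unit_system: str
    new_loinc_code: str
    new_loinc_display: str
    new_loinc_system: str

    @property
    def key(self) -> tuple[str, str]:
        return (self.old_loinc_code, self.unit_code)


@dataclass(frozen=True)
class LRREntry:
    """Reasonable-range metadata for one LOINC code, in its preferred unit."""

    loinc_code: str
    loinc_name: str
    unit: UnitConcept
    min_reasonable: float
    max_reasonable: float
    mean: float
    median: float

    def __post_init__(self) -> None:
        if not self.min_reasonable < self.max_reasonable:
            raise IntegrityError(
                f"LRR {self.loinc_code}: min_reasonable must be < max_reasonable "
                f"({self.min_reasonable!r} vs {self.max_reasonable!r})"
            )
        if not (self.min_reasonable <= self.median <= self.max_reasonable):
            raise IntegrityError(
                f"LRR {self.loinc_code}: median {self.median!r} outside "
                f"[{self.min_reasonable!r}, {self.max_reasonable!r}]"
            )


@dataclass(frozen=True)
class UMMEntry:
    """One unit relationship: incorrect/absent unit -> preferred unit.

    ``incorrect_unit is None`` encodes the null-unit case used to populate
    absent units (null-fill). ``value' = value * multiplier + scalar_constant``;
    the scalar is only nonzero for temperature conversions.
    """

    incorrect_unit: UnitConcept | None
    correct_unit: UnitConcept
    multiplier: float
    scalar_constant: float
    multiplier_type: str

    def __post_init__(self) -> None:
        if self.multiplier_type not in MULTIPLIER_TYPES:
            raise IntegrityError(
                f"unknown multiplier_type {self.multiplier_type!r}"
            )
        if not self.multiplier > 0:
            raise IntegrityError(
                f"UMM {self.key}: multiplier must be positive, "
                f"got {self.multiplier!r}"
            )
        if self.multiplier_type in ("nullfill", "synonym", "unit_typo"):
            if self.multiplier != 1 or self.scalar_constant != 0:
                raise IntegrityError(
                    f"UMM {self.key}: {self.multiplier_type} rows must preserve "
                    f"the value (multiplier 1, scalar 0)"
                )
        if self.multiplier_type == "nullfill" and self.incorrect_unit is not None:
            raise IntegrityError(
                f"UMM {self.key}: nullfill rows must have an empty incorrect unit"
            )

    @property
    def incorrect_code(self) -> str:
        """The incorrect unit code, or '' for the null-unit row."""
        return self.incorrect_unit.code if self.incorrect_unit else ""

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.incorrect_code, self.correct_unit.code, self.multiplier_type)

    def transform(self, value: float) -> float:
        return value * self.multiplier + self.scalar_constant


@dataclass
class KnowledgeBase:
    """The three indexed knowledge tables with cross-table integrity.

    Indexes:
      * ``lcm`` by ``(old_loinc_code, unit_code)``
      * ``lrr`` by ``loinc_code``
      * ``umm`` by ``(incorrect_unit_code or '', correct_unit_code,
        multiplier_type)`` with a secondary index by incorrect code.
    """

    lcm: dict[tuple[str, str], LCMEntry] = field(default_factory=dict)
    lrr: dict[str, LRREntry] = field(default_factory=dict)
    umm: dict[tuple[str, str, str], UMMEntry] = field(default_factory=dict)
    strict: bool = True

    def __post_init__(self) -> None:
        self._umm_by_incorrect: dict[str, list[UMMEntry]] = {}
        for entry in self.umm.values():
            self._umm_by_incorrect.setdefault(entry.incorrect_code, []).append(entry)
        self.validate()

    def umm_for_unit(self, unit_code: str | None) -> list[UMMEntry]:
        """All UMM rows whose incorrect unit matches ``unit_code``.

        ``None`` selects the null-unit (nullfill) rows.
        """
        return list(self._umm_by_incorrect.get(unit_code or "", ()))

    def validate(self) -> None:
        """Re-check cross-table referential integrity."""
        if not self.strict:
            return
        for entry in self.lcm.values():
            if entry.new_loinc_code not in self.lrr:
                raise ReferentialError(
                    f"LCM target {entry.new_loinc_code!r} (from "
                    f"{entry.key!r}) has no LRR entry"
                )


# ---------------------------------------------------------------------------
# CSV loading / writing


def _unit_from_row(row: Mapping[str, object], prefix: str,
                   default_system: str = SNOMED_URI) -> UnitConcept | None:
    code = str(row.get(f"{prefix}_code", "") or "").strip()
    if not code:
        return None
    display = str(row.get(f"{prefix}_name", row.get(f"{prefix}_display", "")) or "")
    system = str(row.get(f"{prefix}_system", "") or "") or default_system
    return UnitConcept(code=code, display=display, system=system)


def _require_columns(df: pd.DataFrame, required: Iterable[str], table: str,
                     path: object) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableParseError(
            f"{table} table {path}: missing columns {missing}"
        )


def _to_float(raw: object, table: str, column: str, row_number: int) -> float:
    try:
        value = float(raw)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        raise TableParseError(
            f"{table} row {row_number}: non-numeric {column}={raw!r}"
        ) from None
    if not math.isfinite(value):
        raise TableParseError(
            f"{table} row {row_number}: non-finite {column}={raw!r}"
        )
    return value


def _read_csv(path: object) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    return df


def lcm_from_frame(df: pd.DataFrame, path: object = "<frame>") -> dict[tuple[str, str], LCMEntry]:
    _require_columns(df, ["old_loinc_code", "unit_code", "new_loinc_code"], "LCM", path)
    entries: dict[tuple[str, str], LCMEntry] = {}
    for i, row in enumerate(df.to_dict("records"), start=2):
        entry = LCMEntry(
            old_loinc_code=str(row["old_loinc_code"]).strip(),
            old_loinc_display=str(row.get("old_loinc_display", "")),
            old_loinc_system=str(row.get("old_loinc_system", "")) or LOINC_URI,
            unit_code=str(row["unit_code"]).strip(),
            unit_display=str(row.get("unit_display", "")),
            unit_system=str(row.get("unit_system", "")) or SNOMED_URI,
            new_loinc_code=str(row["new_loinc_code"]).strip(),
            new_loinc_display=str(row.get("new_loinc_display", "")),
            new_loinc_system=str(row.get("new_loinc_system", "")) or LOINC_URI,
        )
        if entry.new_loinc_code == entry.old_loinc_code:
            raise IntegrityError(
                f"LCM row {i}: new_loinc_code equals old_loinc_code "
                f"({entry.old_loinc_code!r})"
            )
        if entry.key in entries:
            raise IntegrityError(f"LCM duplicate primary key {entry.key!r}")
        entries[entry.key] = entry
    return entries


def lrr_from_frame(df: pd.DataFrame, path: object = "<frame>") -> dict[str, LRREntry]:
    _require_columns(df, LRR_COLUMNS, "LRR", path)
    entries: dict[str, LRREntry] = {}
    for i, row in enumerate(df.to_dict("records"), start=2):
        unit = _unit_from_row(row, "unit")
        if unit is None:
            raise IntegrityError(f"LRR row {i}: missing unit_code")
        entry = LRREntry(
            loinc_code=str(row["loinc_code"]).strip(),
            loinc_name=str(row.get("loinc_name", "")),
            unit=unit,
            min_reasonable=_to_float(row["min_reasonable"], "LRR", "min_reasonable", i),
            max_reasonable=_to_float(row["max_reasonable"], "LRR", "max_reasonable", i),
            mean=_to_float(row["mean"], "LRR", "mean", i),
            median=_to_float(row["median"], "LRR", "median", i),
        )
        if entry.loinc_code in entries:
            raise IntegrityError(f"LRR duplicate primary key {entry.loinc_code!r}")
        entries[entry.loinc_code] = entry
    return entries


def umm_from_frame(df: pd.DataFrame, path: object = "<frame>") -> dict[tuple[str, str, str], UMMEntry]:
    _require_columns(df, UMM_COLUMNS, "UMM", path)
    entries: dict[tuple[str, str, str], UMMEntry] = {}
    for i, row in enumerate(df.to_dict("records"), start=2):
        correct = _unit_from_row(row, "correct_unit")
        if correct is None:
            raise IntegrityError(f"UMM row {i}: missing correct_unit_code")
        entry = UMMEntry(
            incorrect_unit=_unit_from_row(row, "incorrect_unit"),
            correct_unit=correct,
            multiplier=_to_float(row["multiplier"], "UMM", "multiplier", i),
            scalar_constant=_to_float(row["scalar_constant"], "UMM", "scalar_constant", i),
            multiplier_type=str(row["multiplier_type"]).strip(),
        )
        if entry.key in entries:
            raise IntegrityError(f"UMM duplicate primary key {entry.key!r}")
        entries[entry.key] = entry
    return entries


def build_knowledge_base(
    lcm_df: pd.DataFrame,
    lrr_df: pd.DataFrame,
    umm_df: pd.DataFrame,
    *,
    strict: bool = True,
) -> KnowledgeBase:
    """Assemble a validated KnowledgeBase from three dataframes.

    ``strict=True`` enforces that every LCM target LOINC code has an LRR entry
    (recommended; without it the engine cannot range-gate a conversion).
    """
    return KnowledgeBase(
        lcm=lcm_from_frame(lcm_df),
        lrr=lrr_from_frame(lrr_df),
        umm=umm_from_frame(umm_df),
        strict=strict,
    )


def load_knowledge_base(
    lcm_path: str | Path,
    lrr_path: str | Path,
    umm_path: str | Path,
    *,
    strict: bool = True,
) -> KnowledgeBase:
    """Load the three knowledge tables from CSV files.

    The load is deterministic and order-independent; all single-table and
    cross-table invariants are validated before the KnowledgeBase is returned.
    """
    return build_knowledge_base(
        _read_csv(lcm_path), _read_csv(lrr_path), _read_csv(umm_path),
        strict=strict,
    )


def knowledge_base_frames(kb: KnowledgeBase) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """The three tables as dataframes with the canonical column names."""
    lcm_rows = [
        {
            "old_loinc_code": e.old_loinc_code,
            "old_loinc_display": e.old_loinc_display,
            "old_loinc_system": e.old_loinc_system,
            "unit_code": e.unit_code,
            "unit_display": e.unit_display,
            "unit_system": e.unit_system,
            "new_loinc_code": e.new_loinc_code,
            "new_loinc_display": e.new_loinc_display,
            "new_loinc_system": e.new_loinc_system,
        }
        for e in kb.lcm.values()
    ]
    lrr_rows = [
        {
            "loinc_code": e.loinc_code,
            "loinc_name": e.loinc_name,
            "unit_code": e.unit.code,
            "unit_name": e.unit.display,
            "unit_system": e.unit.system,
            "min_reasonable": e.min_reasonable,
            "max_reasonable": e.max_reasonable,
            "mean": e.mean,
            "median": e.median,
        }
        for e in kb.lrr.values()
    ]
    umm_rows = [
        {
            "incorrect_unit_code": e.incorrect_code,
            "incorrect_unit_name": e.incorrect_unit.display if e.incorrect_unit else "",
            "incorrect_unit_system": e.incorrect_unit.system if e.incorrect_unit else "",
            "correct_unit_code": e.correct_unit.code,
            "correct_unit_name": e.correct_unit.display,
            "correct_unit_system": e.correct_unit.system,
            "multiplier": e.multiplier,
            "scalar_constant": e.scalar_constant,
            "multiplier_type": e.multiplier_type,
        }
        for e in kb.umm.values()
    ]
    return (
        pd.DataFrame(lcm_rows, columns=LCM_COLUMNS),
        pd.DataFrame(lrr_rows, columns=LRR_COLUMNS + ["unit_system"]),
        pd.DataFrame(umm_rows, columns=UMM_COLUMNS + ["incorrect_unit_system",
                                                      "correct_unit_system"]),
    )


def write_knowledge_base(kb: KnowledgeBase, lcm_path: str | Path,
                         lrr_path: str | Path, umm_path: str | Path) -> None:
    """Write the three tables back to CSV (round-trips with the loader)."""
    lcm_df, lrr_df, umm_df = knowledge_base_frames(kb)
    lcm_df.to_csv(lcm_path, index=False)
    lrr_df.to_csv(lrr_path, index=False)
    umm_df.to_csv(umm_path, index=False)


# ---------------------------------------------------------------------------
# Empirical derivation


def empirical_quantiles(values: Sequence[float] | np.ndarray) -> dict[float, float]:
    """Summarize a value distribution at the canonical probabilities.

    Uses linear interpolation between order statistics (type 7). Non-finite
    values are dropped; at least two finite values are required.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise InsufficientDataError(
            f"need at least 2 finite values, got {arr.size}"
        )
    qs = np.quantile(arr, QUANTILE_PROBS, method="linear")
    return dict(zip(QUANTILE_PROBS, (float(q) for q in qs)))


def derive_lrr_entry(
    loinc_code: str,
    records: Sequence,
    unit_counts: Mapping[UnitConcept, int],
    *,
    loinc_name: str = "",
    padding: float = 0.0,
) -> LRREntry:
    """Derive a reasonable-range entry for one LOINC code from a corpus.

    The preferred unit is the highest-frequency unit in ``unit_counts``
    (a tie raises :class:`UnitTieError` — no tiebreak is defined, so the
    ambiguity is surfaced to the curator). The range is the [0.005, 0.995]
    empirical quantile interval of the record values, optionally widened by
    ``padding`` (a fraction of the interval width on each side; default 0).

    ``records`` must all carry ``loinc_code`` and numeric values expressed in
    the winning unit.
    """
    if not unit_counts:
        raise InsufficientDataError("unit_counts is empty")
    top = max(unit_counts.values())
    winners = [u for u, c in unit_counts.items() if c == top]
    if len(winners) > 1:
        raise UnitTieError([u.code for u in winners])
    unit = winners[0]

    values = [r.value for r in records]
    q = empirical_quantiles(values)
    lo, hi = q[0.005], q[0.995]
    pad = padding * (hi - lo)
    name = loinc_name or (records[0].loinc_display if records else "")
    return LRREntry(
        loinc_code=loinc_code,
        loinc_name=name,
        unit=unit,
        min_reasonable=lo - pad,
        max_reasonable=hi + pad,
        mean=float(np.mean(values)),
        median=q[0.5],
    )
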