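"""Curated demonstration knowledge tables.

Two tiers are provided:

* :func:`core_tables` — the minimal worked-example rows covering platelet
  counts, blood glucose and kappa light chains (4 LCM rows, 3 LRR rows,
  7 UMM rows). The LCM targets (28542-9, 15074-8, 17096-9) deliberately have
  no LRR rows here, so a strict load fails referential validation; use
  ``strict=False`` or the demo tier.
* :func:`demo_tables` — the core rows plus **synthetic** extensions that make
  the set referentially complete and give every correctable error pattern at
  least one supporting row: LRR entries for the three conversion-target LOINC
  codes (clinically plausible ranges, chosen once), a null-fill row for
  mg/dL, a mEq/L→mmol/L synonym row, and a synonym row with a synthetic unit
  code standing in for the legacy "mg/100mL" spelling of mg/dL.

Unit codes are SNOMED CT by default; :func:`to_ucum` rewrites every unit code
in the tables to its UCUM equivalent, leaving the engine untouched — the
engine matches codes only, so the swap requires no other change.
"""

from __future__ import annotations

import pandas as pd

from .knowledge import (
    UCUM_URI,
    KnowledgeBase,
    UnitConcept,
    build_knowledge_base,
)

__all__ = [
    "UNITS",
    "SNOMED_TO_UCUM",
    "core_tables",
    "demo_tables",
    "core_knowledge_base",
    "demo_knowledge_base",
    "to_ucum",
    "write_tables",
]

#: SNOMED-coded units used across the demonstration tables.
UNITS = {
    "x10E3/uL": UnitConcept("1287856009", "×10(3)/mcL"),
    "10*9/L": UnitConcept("277288007", "10*9/L"),
    "cells/uL": UnitConcept("258878000", "cells/µL"),
    "fL": UnitConcept("258775009", "fL"),
    "g/dL": UnitConcept("258795003", "g/dL"),
    "mg/dL": UnitConcept("258797006", "mg/dL"),
    "g/L": UnitConcept("258794004", "g/L"),
    "mg/L": UnitConcept("258796002", "mg/L"),
    "mmol/L": UnitConcept("258813002", "mmol/L"),
    "mEq/L": UnitConcept("258865000", "mEq/L"),
    "percent": UnitConcept("118582008", "Percentage"),
    # synthetic concept code: legacy spelling of mg/dL seen in source data
    "mg/100mL": UnitConcept("999000990108", "mg/100mL"),
}

#: Code translation applied by :func:`to_ucum`.
SNOMED_TO_UCUM = {
    "1287856009": "10*3/uL",
    "277288007": "10*9/L",
    "258878000": "{cells}/uL",
    "258775009": "fL",
    "258795003": "g/dL",
    "258797006": "mg/dL",
    "258794004": "g/L",
    "258796002": "mg/L",
    "258813002": "mmol/L",
    "258865000": "meq/L",
    "118582008": "%",
    "999000990108": "mg/(100.mL)",
}

_LOINC = {
    "26515-7": "Platelets (#/volume) in blood",
    "28542-9": "Platelet (entitic mean volume) in blood",
    "2339-0": "Glucose (mass/volume) in blood",
    "15074-8": "Glucose (moles/volume) in blood",
    "11050-2": "Kappa light chains (mass/volume) in serum or plasma",
    "17096-9": "Kappa lymphocytes/lymphocytes in blood",
}


def _lcm_row(old: str, unit_key: str, new: str) -> dict:
    unit = UNITS[unit_key]
    return {
        "old_loinc_code": old, "old_loinc_display": _LOINC[old],
        "old_loinc_system": "http://loinc.org",
        "unit_code": unit.code, "unit_display": unit.display,
        "unit_system": unit.system,
        "new_loinc_code": new, "new_loinc_display": _LOINC[new],
        "new_loinc_system": "http://loinc.org",
    }


def _lrr_row(loinc: str, unit_key: str, lo: float, hi: float,
             median: float, mean: float) -> dict:
    unit = UNITS[unit_key]
    return {
        "loinc_code": loinc, "loinc_name": _LOINC[loinc],
        "unit_code": unit.code, "unit_name": unit.display,
        "unit_system": unit.system,
        "min_reasonable": lo, "max_reasonable": hi,
        "mean": mean, "median": median,
    }


def _umm_row(incorrect_key: str | None, correct_key: str, multiplier: float,
             scalar: float, mtype: str) -> dict:
    incorrect = UNITS[incorrect_key] if incorrect_key else None
    correct = UNITS[correct_key]
    return {
        "incorrect_unit_code": incorrect.code if incorrect else "",
        "incorrect_unit_name": incorrect.display if incorrect else "",
        "incorrect_unit_system": incorrect.system if incorrect else "",
        "correct_unit_code": correct.code, "correct_unit_name": correct.display,
        "correct_unit_system": correct.system,
        "multiplier": multiplier, "scalar_constant": scalar,
        "multiplier_type": mtype,
    }


def core_tables() -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """The minimal worked-example rows (LCM, LRR, UMM dataframes)."""
    lcm = pd.DataFrame([
        _lcm_row("26515-7", "fL", "28542-9"),
        _lcm_row("2339-0", "mEq/L", "15074-8"),
        _lcm_row("2339-0", "mmol/L", "15074-8"),
        _lcm_row("11050-2", "percent", "17096-9"),
    ])
    lrr = pd.DataFrame([
        _lrr_row("26515-7", "x10E3/uL", 1, 800, 223.5, 215.0),
        _lrr_row("2339-0", "mg/dL", 40, 400, 138.8, 121),
        _lrr_row("11050-2", "mg/L", 0.1, 5000, 68.7, 25.9),
    ])
    umm = pd.DataFrame([
        _umm_row(None, "x10E3/uL", 1, 0, "nullfill"),
        _umm_row("10*9/L", "x10E3/uL", 1, 0, "synonym"),
        _umm_row("cells/uL", "x10E3/uL", 0.001, 0, "unit_conversion"),
        _umm_row("cells/uL", "x10E3/uL", 1, 0, "unit_typo"),
        _umm_row("g/dL", "mg/dL", 1000, 0, "unit_conversion"),
        _umm_row("g/dL", "mg/dL", 1, 0, "unit_typo"),
        _umm_row("g/L", "mg/dL", 1, 0, "unit_conversion"),
    ])
    return lcm, lrr, umm


def demo_tables() -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Core rows plus synthetic extensions (referentially complete)."""
    lcm, lrr, umm = core_tables()
    lrr_extra = pd.DataFrame([
        # synthetic: plausible mean platelet volume distribution
        _lrr_row("28542-9", "fL", 5, 15, 9.8, 9.9),
        # synthetic: plausible blood glucose molarity distribution
        _lrr_row("15074-8", "mmol/L", 2.2, 22.2, 7.7, 6.7),
        # synthetic: plausible kappa/lymphocyte percentage distribution
        _lrr_row("17096-9", "percent", 10, 95, 60.0, 58.0),
    ])
    umm_extra = pd.DataFrame([
        _umm_row(None, "mg/dL", 1, 0, "nullfill"),
        _umm_row("mEq/L", "mmol/L", 1, 0, "synonym"),
        _umm_row("mg/100mL", "mg/dL", 1, 0, "synonym"),
    ])
    return (
        lcm,
        pd.concat([lrr, lrr_extra], ignore_index=True),
        pd.concat([umm, umm_extra], ignore_index=True),
    )


def core_knowledge_base(*, strict: bool = False) -> KnowledgeBase:
    """KnowledgeBase from the core rows (non-strict by default: the core LCM
    targets have no LRR rows, so a strict build raises a referential error)."""
    return build_knowledge_base(*core_tables(), strict=strict)


def demo_knowledge_base() -> KnowledgeBase:
    """Strictly validated KnowledgeBase from the demo tables."""
    return build_knowledge_base(*demo_tables(), strict=True)


def to_ucum(
    tables: tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame],
    mapping: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Rewrite every unit code in the tables to its UCUM equivalent.

    Only the tables change; the engine is untouched. A unit code missing from
    ``mapping`` raises ``KeyError`` so silent partial translation is
    impossible.
    """
    mapping = SNOMED_TO_UCUM if mapping is None else mapping
    lcm, lrr, umm = (t.copy() for t in tables)

    def translate(code: str) -> str:
        if code == "":
            return ""
        return mapping[code]

    lcm["unit_code"] = lcm["unit_code"].map(translate)
    lcm["unit_system"] = UCUM_URI
    lrr["unit_code"] = lrr["unit_code"].map(translate)
    lrr["unit_system"] = UCUM_URI
    umm["incorrect_unit_code"] = umm["incorrect_unit_code"].map(translate)
    umm["incorrect_unit_system"] = [
        UCUM_URI if c else "" for c in umm["incorrect_unit_code"]
    ]
    umm["correct_unit_code"] = umm["correct_unit_code"].map(translate)
    umm["correct_unit_system"] = UCUM_URI
    return lcm, lrr, umm


def write_tables(
    tables: tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame],
    lcm_path, lrr_path, umm_path,
) -> None:
    """Write the three dataframes as CSV files."""
    lcm, lrr, umm = tables
    lcm.to_csv(lcm_path, index=False)
    lrr.to_csv(lrr_path, index=False)
    umm.to_csv(umm_path, index=False)
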