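"""Seeded synthetic laboratory records with known ground truth.

The generator draws clean, conformant records from per-LOINC value
distributions anchored at the LRR median and truncated to the reasonable
range, then injects the error patterns the knowledge tables are built to
correct — unit synonyms, missing units, scale typos, convertible units,
LOINC-incompatible units — plus an unrecoverable pattern (a unit code absent
from every table). Each corrupted record is paired with its clean original,
so engine recovery can be measured exactly without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .engine import (
    LabRecord,
    harmonize_record,
    in_range,
)
from .knowledge import KnowledgeBase, LRREntry, UnitConcept

__all__ = [
    "ERROR_KINDS",
    "DEFAULT_ERROR_MIX",
    "RECOVERABLE_MIX",
    "RECOVERY_LOINC_CODES",
    "UNRECOVERABLE_UNIT",
    "SynthConfig",
    "GroundTruthPair",
    "SynthConfigError",
    "generate_clean",
    "inject_errors",
    "generate_pairs",
    "recovery_rate",
]

ERROR_KINDS = ("none", "synonym", "missing_unit", "scale_typo",
               "convertible", "loinc_incompatible", "unrecoverable")

#: Default corruption mix: most records arrive clean, missing units are the
#: most common defect, and a small unrecoverable tail is always present —
#: the qualitative shape observed in multi-source EHR laboratory feeds.
DEFAULT_ERROR_MIX = {
    "none": 0.70,
    "missing_unit": 0.08,
    "synonym": 0.06,
    "convertible": 0.06,
    "scale_typo": 0.05,
    "loinc_incompatible": 0.03,
    "unrecoverable": 0.02,
}

#: Corruption mix for recovery studies: only patterns the knowledge tables
#: can reverse, plus a small clean fraction. Paired with
#: :data:`RECOVERY_LOINC_CODES`, every quota is satisfiable.
RECOVERABLE_MIX = {
    "synonym": 0.23,
    "missing_unit": 0.23,
    "convertible": 0.23,
    "loinc_incompatible": 0.23,
    "none": 0.08,
}

#: Corpus composition for recovery studies: the unit-error corruptions need
#: codes with unit multiplier rows (platelets, glucose mass/volume —
#: upweighted), while LOINC-incompatibility corruptions need codes that are
#: conversion targets.
RECOVERY_LOINC_CODES = (
    "26515-7", "2339-0", "26515-7", "2339-0", "26515-7", "2339-0",
    "26515-7", "2339-0", "28542-9", "15074-8", "17096-9",
)

#: Unit concept guaranteed absent from every knowledge table.
UNRECOVERABLE_UNIT = UnitConcept("000000000", "unmapped unit")


class SynthConfigError(ValueError):
    """The generator configuration is unsatisfiable."""


@dataclass
class SynthConfig:
    """Study conditions for one synthetic corpus.

    ``error_mix`` proportions must be nonnegative and sum to 1; record counts
    per error kind are exact (largest-remainder apportionment), so designed
    proportions are hit exactly, not just in expectation. ``value_model`` is
    ``"lognormal"`` (median-anchored, default) or ``"truncnorm"``;
    ``edge_margin`` shrinks the sampling interval away from the range edges
    by that fraction of the range width on each side.
    """

    n: int
    seed: int = 0
    error_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ERROR_MIX))
    loinc_codes: tuple[str, ...] | None = None
    value_model: str = "lognormal"
    sigma: float = 0.35
    edge_margin: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise SynthConfigError(f"n must be >= 1, got {self.n}")
        unknown = set(self.error_mix) - set(ERROR_KINDS)
        if unknown:
            raise SynthConfigError(f"unknown error kinds: {sorted(unknown)}")
        if any(p < 0 for p in self.error_mix.values()):
            raise SynthConfigError("error_mix proportions must be nonnegative")
        total = sum(self.error_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise SynthConfigError(f"error_mix must sum to 1, got {total}")
        if self.value_model not in ("lognormal", "truncnorm"):
            raise SynthConfigError(f"unknown value_model {self.value_model!r}")
        if not 0 <= self.edge_margin < 0.5:
            raise SynthConfigError("edge_margin must lie in [0, 0.5)")


@dataclass
class GroundTruthPair:
    """A clean record, its corrupted twin, and the injected error kind.

    ``ambiguous`` marks corruptions where more than one transformation chain
    lands in the reasonable range (or an unintended LOINC conversion applies),
    so even a perfect engine may legitimately pick the other reading.
    """

    clean: LabRecord
    corrupted: LabRecord
    injected_error: str
    ambiguous: bool = False


def _sample_interval(lrr: LRREntry, margin: float) -> tuple[float, float]:
    span = lrr.max_reasonable - lrr.min_reasonable
    return (lrr.min_reasonable + margin * span,
            lrr.max_reasonable - margin * span)


def _draw_values(rng: np.random.Generator, lrr: LRREntry, n: int,
                 config: SynthConfig) -> np.ndarray:
    lo, hi = _sample_interval(lrr, config.edge_margin)
    if not lo <= lrr.median <= hi and config.edge_margin == 0:
        raise SynthConfigError(
            f"{lrr.loinc_code}: range excludes the median anchor")
    if config.value_model == "lognormal":
        if lrr.median <= 0:
            raise SynthConfigError(
                f"{lrr.loinc_code}: lognormal model needs a positive median "
                f"anchor; use value_model='truncnorm'")
        mu = np.log(lrr.median)
        draw = lambda k: rng.lognormal(mu, config.sigma, k)
    else:
        scale = (lrr.max_reasonable - lrr.min_reasonable) / 6
        draw = lambda k: rng.normal(lrr.median, scale, k)
    out = np.empty(0)
    for _ in range(1000):  # rejection sampling into [lo, hi]
        batch = draw(max(n, 32))
        out = np.concatenate([out, batch[(batch >= lo) & (batch <= hi)]])
        if out.size >= n:
            return out[:n]
    raise SynthConfigError(
        f"{lrr.loinc_code}: could not draw in-range values "
        f"(acceptance region too small)")


def generate_clean(kb: KnowledgeBase, config: SynthConfig) -> list[LabRecord]:
    """Draw conformant, in-range records, round-robin over the LOINC codes.

    Deterministic given ``config.seed``: identical configs yield identical
    record lists.
    """
    codes = config.loinc_codes or tuple(sorted(kb.lrr))
    missing = [c for c in codes if c not in kb.lrr]
    if missing:
        raise SynthConfigError(f"LOINC codes without LRR entries: {missing}")
    rng = np.random.default_rng(config.seed)
    # repeated codes in the tuple weight the round-robin toward those codes
    per_code: dict[str, int] = {}
    for i in range(config.n):
        c = codes[i % len(codes)]
        per_code[c] = per_code.get(c, 0) + 1
    values = {c: iter(_draw_values(rng, kb.lrr[c], per_code[c], config))
              for c in sorted(per_code)}
    records = []
    for i in range(config.n):
        code = codes[i % len(codes)]
        lrr = kb.lrr[code]
        records.append(LabRecord(
            record_id=f"syn-{i:06d}",
            loinc_code=code,
            loinc_display=lrr.loinc_name,
            unit=lrr.unit,
            value=float(next(values[code])),
        ))
    return records


# ---------------------------------------------------------------------------
# Error injection


def _support_rows(kb: KnowledgeBase, loinc_code: str):
    """Table rows usable to corrupt a record with this LOINC code."""
    lrr = kb.lrr[loinc_code]
    preferred = lrr.unit.code
    umm_in = [e for e in kb.umm.values() if e.correct_unit.code == preferred]
    return {
        "synonym": [e for e in umm_in
                    if e.multiplier_type == "synonym" and e.incorrect_unit],
        "missing_unit": [e for e in umm_in if e.multiplier_type == "nullfill"],
        "scale_typo": [e for e in umm_in
                       if e.multiplier_type == "unit_typo" and e.incorrect_unit],
        "convertible": [e for e in umm_in
                        if e.multiplier_type == "unit_conversion"
                        and e.incorrect_unit],
        "loinc_incompatible": [e for e in kb.lcm.values()
                               if e.new_loinc_code == loinc_code],
    }


def _is_ambiguous(corrupted: LabRecord, kb: KnowledgeBase) -> bool:
    """More than one plausible reading of the corrupted record exists."""
    lrr = kb.lrr.get(corrupted.loinc_code)
    if lrr is None:
        return False
    unit_code = corrupted.unit.code if corrupted.unit else None
    if corrupted.unit is not None and \
            (corrupted.loinc_code, unit_code) in kb.lcm:
        return True
    in_range_values = {
        round(e.transform(corrupted.value), 12)
        for e in kb.umm_for_unit(unit_code)
        if e.correct_unit.code == lrr.unit.code
        and in_range(e.transform(corrupted.value), lrr)
    }
    return len(in_range_values) > 1


def _quotas(mix: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n records across error kinds."""
    exact = {k: mix.get(k, 0.0) * n for k in ERROR_KINDS}
    counts = {k: int(np.floor(v)) for k, v in exact.items()}
    short = n - sum(counts.values())
    remainders = sorted(exact, key=lambda k: (exact[k] - counts[k]), reverse=True)
    for k in remainders[:short]:
        counts[k] += 1
    return counts


def _corrupt(record: LabRecord, kind: str, rows, rng: np.random.Generator,
             kb: KnowledgeBase) -> LabRecord:
    out = record.copy()
    if kind == "none":
        return out
    if kind == "unrecoverable":
        out.unit = UNRECOVERABLE_UNIT
        return out
    row = rows[rng.integers(len(rows))]
    if kind == "missing_unit":
        out.unit = None
    elif kind in ("synonym", "scale_typo"):
        out.unit = row.incorrect_unit
    elif kind == "convertible":
        out.unit = row.incorrect_unit
        # inverse of value' = value * m + s, so harmonization restores it
        out.value = (record.value - row.scalar_constant) / row.multiplier
    elif kind == "loinc_incompatible":
        out.loinc_code = row.old_loinc_code
        out.loinc_display = row.old_loinc_display
        out.unit = UnitConcept(row.unit_code, row.unit_display,
                               row.unit_system)
    return out


def inject_errors(
    clean: Sequence[LabRecord], kb: KnowledgeBase, config: SynthConfig
) -> list[GroundTruthPair]:
    """Corrupt clean records according to the configured error mix.

    Error-kind counts are exact. Each kind is assigned only to records whose
    LOINC code has supporting table rows; an unsatisfiable quota raises
    :class:`SynthConfigError` naming the gap. Output order follows the input.
    """
    rng = np.random.default_rng(config.seed + 1)
    quotas = _quotas(config.error_mix, len(clean))
    support = {r.record_id: _support_rows(kb, r.loinc_code) for r in clean}

    unassigned = set(range(len(clean)))
    assignment: dict[int, str] = {}
    # scarce kinds first; 'none' and 'unrecoverable' are universally supported
    for kind in ("loinc_incompatible", "synonym", "scale_typo", "convertible",
                 "missing_unit", "unrecoverable", "none"):
        need = quotas.get(kind, 0)
        if need == 0:
            continue
        if kind in ("none", "unrecoverable"):
            eligible = sorted(unassigned)
        else:
            eligible = sorted(
                i for i in unassigned
                if support[clean[i].record_id][kind]
            )
        if len(eligible) < need:
            raise SynthConfigError(
                f"error kind {kind!r}: need {need} records but only "
                f"{len(eligible)} have supporting knowledge-table rows"
            )
        chosen = rng.choice(len(eligible), size=need, replace=False)
        for j in chosen:
            assignment[eligible[j]] = kind
        unassigned -= {eligible[j] for j in chosen}

    pairs = []
    for i, record in enumerate(clean):
        kind = assignment[i]
        rows = support[record.record_id].get(kind, [])
        corrupted = _corrupt(record, kind, rows, rng, kb)
        ambiguous = (kind in ("scale_typo", "convertible")
                     and _is_ambiguous(corrupted, kb))
        pairs.append(GroundTruthPair(clean=record, corrupted=corrupted,
                                     injected_error=kind, ambiguous=ambiguous))
    return pairs


def generate_pairs(kb: KnowledgeBase, config: SynthConfig) -> list[GroundTruthPair]:
    """Convenience: generate clean records and inject the configured errors."""
    return inject_errors(generate_clean(kb, config), kb, config)


def _recovered(pair: GroundTruthPair, kb: KnowledgeBase,
               rel_tol: float = 1e-9) -> bool:
    rec = harmonize_record(pair.corrupted, kb).record
    if rec.loinc_code != pair.clean.loinc_code:
        return False
    rec_unit = rec.unit.code if rec.unit else None
    clean_unit = pair.clean.unit.code if pair.clean.unit else None
    if rec_unit != clean_unit:
        return False
    denom = max(abs(pair.clean.value), 1e-300)
    return abs(rec.value - pair.clean.value) / denom <= rel_tol


def recovery_rate(pairs: Sequence[GroundTruthPair], kb: KnowledgeBase) -> float:
    """Fraction of pairs whose harmonized corrupted record equals the clean
    record on LOINC code, unit code and value (1e-9 relative)."""
    if not pairs:
        raise ValueError("recovery_rate requires at least one pair")
    return sum(_recovered(p, kb) for p in pairs) / len(pairs)
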