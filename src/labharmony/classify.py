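"""Unit error-class taxonomy and before/after data-quality metrics.

Each record's unit is assigned exactly one class relative to the knowledge
base: ``correct``, ``synonym`` (a synonym row maps it to the preferred unit),
``absent``, ``incorrect_loinc_suggestive`` (the pair keys a LOINC conversion
row), ``incorrect_convertible`` (a conversion/typo row applies), or
``incorrect_not_convertible``. Precedence follows the engine's rule order, so
a unit that keys both an LCM row and a UMM row counts as LOINC-suggestive.

The quality metrics mirror the evaluation of a harmonization run: unit
correctness rate, unit completeness rate ("proportion of records with
nonmissing units"), per-LOINC correctness with threshold counts, and
error-class proportions — all computable before and after harmonization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .engine import HarmonizationResult, LabRecord, UnknownLoincError
from .knowledge import KnowledgeBase

__all__ = [
    "ERROR_CLASSES",
    "DEFAULT_THRESHOLDS",
    "QualityReport",
    "UndefinedRateError",
    "AlignmentError",
    "classify_unit",
    "classify_records",
    "correct_unit_rate",
    "completeness_rate",
    "loinc_threshold_counts",
    "error_class_proportions",
    "quality_report",
    "before_after_report",
]

CLASS_CORRECT = "correct"
CLASS_SYNONYM = "synonym"
CLASS_ABSENT = "absent"
CLASS_LOINC = "incorrect_loinc_suggestive"
CLASS_CONVERTIBLE = "incorrect_convertible"
CLASS_NOT_CONVERTIBLE = "incorrect_not_convertible"

ERROR_CLASSES = (CLASS_CORRECT, CLASS_SYNONYM, CLASS_ABSENT,
                 CLASS_LOINC, CLASS_CONVERTIBLE, CLASS_NOT_CONVERTIBLE)

DEFAULT_THRESHOLDS = (0.5, 0.8, 0.9, 0.95, 0.99, 1.0)


class UndefinedRateError(ValueError):
    """A rate was requested over an empty denominator."""


class AlignmentError(ValueError):
    """Before/after inputs are not the same length."""


def classify_unit(record: LabRecord, kb: KnowledgeBase) -> str:
    """Assign the record's unit to exactly one error class.

    Raises :class:`~labharmony.engine.UnknownLoincError` when the LOINC code
    has no LRR entry (callers decide how to count those).
    """
    lrr = kb.lrr.get(record.loinc_code)
    if lrr is None:
        raise UnknownLoincError(record.loinc_code)
    preferred = lrr.unit.code
    if record.unit is None:
        return CLASS_ABSENT
    code = record.unit.code
    if code == preferred:
        return CLASS_CORRECT
    rows = [e for e in kb.umm_for_unit(code)
            if e.correct_unit.code == preferred]
    if any(e.multiplier_type == "synonym" for e in rows):
        return CLASS_SYNONYM
    if (record.loinc_code, code) in kb.lcm:
        return CLASS_LOINC
    if any(e.multiplier_type in ("unit_conversion", "unit_typo") for e in rows):
        return CLASS_CONVERTIBLE
    return CLASS_NOT_CONVERTIBLE


def classify_records(
    records: Iterable[LabRecord], kb: KnowledgeBase
) -> tuple[list[str | None], int]:
    """Classify a batch; unknown-LOINC records get ``None``.

    Returns the per-record labels and the count of unknown-LOINC records
    (excluded from every rate denominator, reported separately).
    """
    labels: list[str | None] = []
    unknown = 0
    for record in records:
        try:
            labels.append(classify_unit(record, kb))
        except UnknownLoincError:
            labels.append(None)
            unknown += 1
    return labels, unknown


def correct_unit_rate(records: Sequence[LabRecord], kb: KnowledgeBase) -> float:
    """Fraction of known-LOINC records whose unit is the preferred unit."""
    labels, unknown = classify_records(records, kb)
    known = len(records) - unknown
    if known == 0:
        raise UndefinedRateError("no records with a known LOINC code")
    return sum(1 for label in labels if label == CLASS_CORRECT) / known


def completeness_rate(records: Sequence[LabRecord]) -> float:
    """Fraction of records with a nonmissing unit."""
    if not records:
        raise UndefinedRateError("no records")
    return sum(1 for r in records if r.unit is not None) / len(records)


def _per_loinc_correctness(
    records: Sequence[LabRecord], kb: KnowledgeBase
) -> dict[str, float]:
    totals: dict[str, int] = {}
    correct: dict[str, int] = {}
    labels, _ = classify_records(records, kb)
    for record, label in zip(records, labels):
        if label is None:
            continue
        totals[record.loinc_code] = totals.get(record.loinc_code, 0) + 1
        if label == CLASS_CORRECT:
            correct[record.loinc_code] = correct.get(record.loinc_code, 0) + 1
    return {code: correct.get(code, 0) / n for code, n in totals.items()}


def loinc_threshold_counts(
    records: Sequence[LabRecord],
    kb: KnowledgeBase,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> dict[float, int]:
    """For each threshold t, the number of LOINC codes with correctness >= t."""
    for t in thresholds:
        if not 0 < t <= 1:
            raise ValueError(f"thresholds must lie in (0, 1], got {t}")
    per_code = _per_loinc_correctness(records, kb)
    return {
        t: sum(1 for rate in per_code.values() if rate >= t)
        for t in thresholds
    }


def error_class_proportions(
    records: Sequence[LabRecord], kb: KnowledgeBase
) -> dict[str, float]:
    """Proportion of known-LOINC records in each error class (sums to 1)."""
    labels, unknown = classify_records(records, kb)
    known = len(records) - unknown
    if known == 0:
        raise UndefinedRateError("no records with a known LOINC code")
    return {
        cls: sum(1 for label in labels if label == cls) / known
        for cls in ERROR_CLASSES
    }


@dataclass
class QualityReport:
    """Data-quality snapshot of one record set against a knowledge base."""

    n_records: int
    n_unknown_loinc: int
    correct_unit_rate: float
    completeness_rate: float
    per_loinc_correctness: dict[str, float]
    threshold_counts: dict[float, int]
    error_class_proportions: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "n_unknown_loinc": self.n_unknown_loinc,
            "correct_unit_rate": self.correct_unit_rate,
            "completeness_rate": self.completeness_rate,
            "per_loinc_correctness": dict(self.per_loinc_correctness),
            "threshold_counts": {str(k): v for k, v in self.threshold_counts.items()},
            "error_class_proportions": dict(self.error_class_proportions),
        }


def quality_report(
    records: Sequence[LabRecord],
    kb: KnowledgeBase,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> QualityReport:
    """Compute all quality metrics for one record set."""
    _, unknown = classify_records(records, kb)
    return QualityReport(
        n_records=len(records),
        n_unknown_loinc=unknown,
        correct_unit_rate=correct_unit_rate(records, kb),
        completeness_rate=completeness_rate(records),
        per_loinc_correctness=_per_loinc_correctness(records, kb),
        threshold_counts=loinc_threshold_counts(records, kb, thresholds),
        error_class_proportions=error_class_proportions(records, kb),
    )


def before_after_report(
    original: Sequence[LabRecord],
    harmonized: Sequence[HarmonizationResult],
    kb: KnowledgeBase,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> tuple[QualityReport, QualityReport]:
    """Quality reports before and after harmonization, order-aligned.

    The engine never un-fills or mis-sets a conforming unit, so the after
    report must dominate the before report on correctness and completeness;
    this is asserted and a violation raises ``RuntimeError`` (it would
    indicate a defective knowledge base or engine).
    """
    if len(original) != len(harmonized):
        raise AlignmentError(
            f"{len(original)} original records vs {len(harmonized)} results"
        )
    before = quality_report(original, kb, thresholds)
    after = quality_report([res.record for res in harmonized], kb, thresholds)
    if after.correct_unit_rate < before.correct_unit_rate:
        raise RuntimeError("correctness rate decreased after harmonization")
    if after.completeness_rate < before.completeness_rate:
        raise RuntimeError("completeness rate decreased after harmonization")
    return before, after
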