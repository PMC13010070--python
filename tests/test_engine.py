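"""Engine unit tests: rule precedence, range gating, conflict resolution,
provenance, and reversibility on the worked examples."""

import pytest

from labharmony.engine import (
    STATUS_CONFORMANT,
    STATUS_OUT_OF_RANGE,
    STATUS_TRANSFORMED,
    STATUS_UNRESOLVED,
    LabRecord,
    LedgerError,
    ProvenanceEntry,
    UnknownLoincError,
    apply_lcm,
    candidate_unit_transforms,
    conforms,
    harmonize_record,
    harmonize_stream,
    in_range,
    resolve_conflict,
    revert,
)
from labharmony.knowledge import LRREntry, UMMEntry, UnitConcept


def record(loinc, unit, value, rid="r"):
    return LabRecord(rid, loinc, unit=unit, value=value)


class TestConformance:
    def test_preferred_unit_conforms(self, kb, units):
        assert conforms(record("26515-7", units["preferred_platelet"], 250), kb)

    def test_other_unit_does_not(self, kb, units):
        assert not conforms(record("26515-7", units["fL"], 9.8), kb)

    def test_missing_unit_never_conforms(self, kb):
        assert not conforms(record("2339-0", None, 100), kb)

    def test_unknown_loinc_signals(self, kb, units):
        with pytest.raises(UnknownLoincError):
            conforms(record("9999-9", units["mg_dL"], 1), kb)


class TestRange:
    @pytest.mark.parametrize(
        ("value", "expected"),
        [(138.8, True), (40, True), (400, True), (0.12, False), (401, False)],
    )
    def test_inclusive_bounds(self, kb, value, expected):
        assert in_range(value, kb.lrr["2339-0"]) is expected


class TestLoincConversion:
    def test_platelet_volume_unit_triggers_conversion(self, kb, units):
        out = apply_lcm(record("26515-7", units["fL"], 9.8), kb)
        assert out.loinc_code == "28542-9"
        assert out.value == 9.8 and out.unit == units["fL"]
        assert [e.rule for e in out.provenance] == ["loinc_conversion"]
        assert out.provenance[0].changed_fields["loinc_code"] == "26515-7"

    def test_kappa_percentage_conversion(self, kb, units):
        out = apply_lcm(record("11050-2", units["percent"], 60.0), kb)
        assert out.loinc_code == "17096-9"

    def test_no_mapping_returns_none(self, kb, units):
        assert apply_lcm(record("2339-0", units["mg_dL"], 100), kb) is None
        assert apply_lcm(record("2339-0", None, 100), kb) is None


class TestUnitCandidates:
    def test_ambiguous_prefix_yields_two_candidates(self, kb, units):
        cands = candidate_unit_transforms(record("2339-0", units["g_dL"], 0.12), kb)
        by_type = {e.multiplier_type: v for e, v in cands}
        assert by_type == {"unit_conversion": pytest.approx(120.0),
                           "unit_typo": pytest.approx(0.12)}

    def test_null_unit_yields_nullfill(self, kb):
        cands = candidate_unit_transforms(record("26515-7", None, 250), kb)
        assert len(cands) == 1
        entry, value = cands[0]
        assert entry.multiplier_type == "nullfill" and value == 250

    def test_unmapped_unit_yields_nothing(self, kb, units):
        assert candidate_unit_transforms(
            record("2339-0", units["unmapped"], 100), kb) == []


class TestConflictResolution:
    def _entry(self, mtype, mult=1.0):
        return UMMEntry(
            incorrect_unit=UnitConcept("111", "x"),
            correct_unit=UnitConcept("222", "y"),
            multiplier=mult, scalar_constant=0.0, multiplier_type=mtype,
        )

    def test_median_proximity_wins(self, kb):
        lrr = kb.lrr["2339-0"]  # median 138.8
        chosen = resolve_conflict(
            [(self._entry("unit_conversion", 1000), 120.0),
             (self._entry("unit_typo"), 130.0)], lrr)
        assert chosen[1] == 130.0

    def test_mean_used_when_median_is_zero(self):
        lrr = LRREntry("x", "x", UnitConcept("1", "u"), -10, 10, mean=2, median=0)
        chosen = resolve_conflict(
            [(self._entry("unit_typo"), 1.0),
             (self._entry("unit_conversion", 5), 5.0)], lrr)
        assert chosen[1] == 1.0

    def test_exact_tie_prefers_value_preserving(self):
        lrr = LRREntry("x", "x", UnitConcept("1", "u"), 0, 200, mean=100, median=100)
        chosen = resolve_conflict(
            [(self._entry("unit_conversion", 2), 90.0),
             (self._entry("unit_typo"), 110.0)], lrr)
        assert chosen[0].multiplier_type == "unit_typo"

    def test_empty_candidates_rejected(self, kb):
        with pytest.raises(ValueError):
            resolve_conflict([], kb.lrr["2339-0"])


class TestHarmonize:
    def test_conformant_record_untouched(self, kb, units):
        res = harmonize_record(record("2339-0", units["mg_dL"], 138.8), kb)
        assert res.status == STATUS_CONFORMANT
        assert res.applied_rules == []
        assert res.record.provenance == []

    def test_conformant_out_of_range_flagged_not_transformed(self, kb, units):
        res = harmonize_record(record("2339-0", units["mg_dL"], 9000), kb)
        assert res.status == STATUS_OUT_OF_RANGE
        assert res.record.value == 9000
        assert "out_of_range" in res.record.flags

    def test_glucose_prefix_error_resolved_by_range(self, kb, units):
        # 0.12 g/dL: typo reading (0.12 mg/dL) is implausible, conversion
        # reading (120 mg/dL) is in range
        res = harmonize_record(record("2339-0", units["g_dL"], 0.12), kb)
        assert res.status == STATUS_TRANSFORMED
        assert res.record.value == pytest.approx(120.0)
        assert res.record.unit.code == "258797006"
        assert res.applied_rules == ["unit_conversion"]

    def test_platelet_fl_unit_changes_loinc(self, kb, units):
        res = harmonize_record(record("26515-7", units["fL"], 9.8), kb)
        assert res.status == STATUS_TRANSFORMED
        assert res.record.loinc_code == "28542-9"
        assert res.record.value == 9.8
        assert res.applied_rules == ["loinc_conversion"]

    def test_conversion_then_normalization_chain(self, kb, units):
        # mEq/L on a mass/volume glucose code: LOINC conversion to the
        # moles/volume code, then synonym normalization to mmol/L
        res = harmonize_record(record("2339-0", units["mEq_L"], 7.7), kb)
        assert res.status == STATUS_TRANSFORMED
        assert res.record.loinc_code == "15074-8"
        assert res.record.unit.code == "258813002"
        assert res.record.value == 7.7
        assert res.applied_rules == ["loinc_conversion", "synonym"]
        assert len(res.record.provenance) == 2

    def test_null_fill_gated_by_range(self, kb):
        blocked = harmonize_record(record("2339-0", None, 500), kb)
        assert blocked.status == STATUS_UNRESOLVED
        assert blocked.record.unit is None
        assert "unresolved" in blocked.record.flags
        filled = harmonize_record(record("2339-0", None, 138.8), kb)
        assert filled.status == STATUS_TRANSFORMED
        assert filled.record.unit.code == "258797006"

    def test_unknown_loinc_passes_through_flagged(self, kb, units):
        res = harmonize_record(record("9999-9", units["mg_dL"], 1.0), kb)
        assert res.status == STATUS_UNRESOLVED
        assert "unknown_loinc" in res.record.flags
        assert res.record.value == 1.0

    def test_input_record_never_mutated(self, kb, units):
        rec = record("2339-0", units["g_dL"], 0.12)
        harmonize_record(rec, kb)
        assert rec.value == 0.12 and rec.unit == units["g_dL"]
        assert rec.provenance == [] and rec.flags == set()


class TestRevert:
    def test_revert_restores_worked_example(self, kb, units):
        res = harmonize_record(record("2339-0", units["g_dL"], 0.12), kb)
        back = revert(res.record)
        assert back.unit == units["g_dL"]
        assert back.value == 0.12
        assert back.loinc_code == "2339-0"

    def test_revert_of_conformant_is_identity(self, kb, units):
        res = harmonize_record(record("2339-0", units["mg_dL"], 138.8), kb)
        back = revert(res.record)
        assert back.unit == units["mg_dL"] and back.value == 138.8

    def test_revert_restores_chained_transformation(self, kb, units):
        res = harmonize_record(record("2339-0", units["mEq_L"], 7.7), kb)
        back = revert(res.record)
        assert (back.loinc_code, back.unit.code, back.value) == \
            ("2339-0", "258865000", 7.7)

    def test_corrupted_ledger_detected(self, kb, units):
        rec = record("2339-0", units["mg_dL"], 100)
        rec.provenance.append(ProvenanceEntry(
            rule="synonym", description="bad",
            changed_fields={"no_such_field": 1}))
        with pytest.raises(LedgerError):
            revert(rec)


class TestStream:
    def test_empty_stream(self, kb):
        results, counts = harmonize_stream([], kb)
        assert results == [] and sum(counts.values()) == 0

    def test_worked_example_counts(self, kb, units):
        records = [
            record("26515-7", units["fL"], 9.8, "a"),
            record("2339-0", units["mg_dL"], 138.8, "b"),
            record("2339-0", None, 500, "c"),
        ]
        results, counts = harmonize_stream(records, kb)
        assert [r.record.record_id for r in results] == ["a", "b", "c"]
        assert counts == {"transformed": 1, "conformant": 1,
                          "unresolved": 1, "out_of_range_flagged": 0}
        assert sum(counts.values()) == len(records)
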