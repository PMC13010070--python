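"""Knowledge-table loading, integrity validation, and empirical derivation."""

import numpy as np
import pandas as pd
import pytest

from labharmony.engine import LabRecord
from labharmony.examples import demo_tables, write_tables
from labharmony.knowledge import (
    QUANTILE_PROBS,
    IntegrityError,
    InsufficientDataError,
    ReferentialError,
    TableParseError,
    UnitTieError,
    build_knowledge_base,
    derive_lrr_entry,
    empirical_quantiles,
    load_knowledge_base,
    write_knowledge_base,
)


class TestLoading:
    def test_core_tables_load_non_strict(self, core_frames):
        kb = build_knowledge_base(*core_frames, strict=False)
        assert (len(kb.lcm), len(kb.lrr), len(kb.umm)) == (4, 3, 7)

    def test_core_tables_fail_referential_check(self, core_frames):
        # the conversion targets have no range entries in the minimal tier
        with pytest.raises(ReferentialError, match="28542-9|15074-8|17096-9"):
            build_knowledge_base(*core_frames, strict=True)

    def test_demo_tables_pass_strict(self, kb):
        assert (len(kb.lcm), len(kb.lrr), len(kb.umm)) == (4, 6, 10)
        kb.validate()  # re-validation holds after load

    def test_csv_round_trip(self, kb, tmp_path):
        paths = [tmp_path / name for name in ("lcm.csv", "lrr.csv", "umm.csv")]
        write_knowledge_base(kb, *paths)
        kb2 = load_knowledge_base(*paths)
        assert kb2.lcm == kb.lcm
        assert kb2.lrr == kb.lrr
        assert kb2.umm == kb.umm

    def test_load_from_paths(self, tmp_path):
        paths = [tmp_path / name for name in ("lcm.csv", "lrr.csv", "umm.csv")]
        write_tables(demo_tables(), *paths)
        kb = load_knowledge_base(*paths)
        assert kb.lrr["2339-0"].median == 138.8
        assert kb.lrr["26515-7"].unit.code == "1287856009"

    def test_duplicate_umm_key_rejected(self, demo_frames):
        lcm, lrr, umm = demo_frames
        dup = pd.concat([umm, umm.iloc[[4]]], ignore_index=True)
        with pytest.raises(IntegrityError, match="258795003"):
            build_knowledge_base(lcm, lrr, dup)

    def test_duplicate_lrr_key_rejected(self, demo_frames):
        lcm, lrr, umm = demo_frames
        dup = pd.concat([lrr, lrr.iloc[[0]]], ignore_index=True)
        with pytest.raises(IntegrityError, match="26515-7"):
            build_knowledge_base(lcm, dup, umm)

    def test_degenerate_range_rejected(self, demo_frames):
        lcm, lrr, umm = demo_frames
        bad = lrr.copy()
        bad.loc[0, "max_reasonable"] = bad.loc[0, "min_reasonable"]
        bad.loc[0, "median"] = bad.loc[0, "min_reasonable"]
        with pytest.raises(IntegrityError, match="min_reasonable"):
            build_knowledge_base(lcm, bad, umm)

    def test_non_numeric_range_names_row(self, demo_frames):
        lcm, lrr, umm = demo_frames
        bad = lrr.copy().astype(object)
        bad.loc[1, "min_reasonable"] = "forty"
        with pytest.raises(TableParseError, match="row 3"):
            build_knowledge_base(lcm, bad, umm)

    def test_value_scaling_rows_must_preserve_value(self, demo_frames):
        lcm, lrr, umm = demo_frames
        bad = umm.copy()
        bad.loc[1, "multiplier"] = 2  # a synonym row must not rescale
        with pytest.raises(IntegrityError, match="synonym"):
            build_knowledge_base(lcm, lrr, bad)


class TestQuantiles:
    def test_median_of_uniform_grid(self):
        q = empirical_quantiles(list(range(1, 1001)))
        assert q[0.5] == pytest.approx(500.5)

    def test_constant_input(self):
        q = empirical_quantiles([5, 5, 5, 5])
        assert all(v == 5 for v in q.values())

    def test_monotone_nondecreasing(self):
        rng = np.random.default_rng(0)
        q = empirical_quantiles(rng.normal(size=500))
        values = [q[p] for p in QUANTILE_PROBS]
        assert values == sorted(values)

    def test_matches_sorting_based_computation(self, kb):
        # oracle: direct linear interpolation on the sorted sample
        from labharmony.synth import SynthConfig, generate_clean
        values = np.array([
            r.value for r in generate_clean(
                kb, SynthConfig(n=10_000, seed=7, loinc_codes=("2339-0",)))
        ])
        srt = np.sort(values)
        n = len(srt)

        def direct(p):
            h = (n - 1) * p
            lo = int(np.floor(h))
            return srt[lo] + (h - lo) * (srt[min(lo + 1, n - 1)] - srt[lo])

        q = empirical_quantiles(values)
        assert q[0.005] == pytest.approx(direct(0.005), rel=1e-12)
        assert q[0.995] == pytest.approx(direct(0.995), rel=1e-12)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            empirical_quantiles([])
        with pytest.raises(InsufficientDataError):
            empirical_quantiles([float("nan"), 1.0])


class TestDerivation:
    @staticmethod
    def _records(values, unit, loinc="2339-0"):
        return [
            LabRecord(f"r{i}", loinc, unit=unit, value=v)
            for i, v in enumerate(values)
        ]

    def test_highest_frequency_unit_wins(self, units):
        mg_dl, mmol = units["mg_dL"], units["mmol_L"]
        entry = derive_lrr_entry(
            "2339-0", self._records([100.0, 120.0, 140.0], mg_dl),
            {mg_dl: 900, mmol: 100},
        )
        assert entry.unit == mg_dl

    def test_single_unit_selected(self, units):
        entry = derive_lrr_entry(
            "2339-0", self._records([90.0, 110.0], units["mg_dL"]),
            {units["mg_dL"]: 2},
        )
        assert entry.unit == units["mg_dL"]

    def test_tie_is_surfaced(self, units):
        with pytest.raises(UnitTieError) as err:
            derive_lrr_entry(
                "2339-0", self._records([1.0, 2.0], units["mg_dL"]),
                {units["mg_dL"]: 5, units["mmol_L"]: 5},
            )
        assert set(err.value.tied_units) == {"258797006", "258813002"}

    def test_range_bounded_by_corpus(self, kb, units):
        # values drawn inside [a, b] must yield a range inside [a, b]
        from labharmony.synth import SynthConfig, generate_clean
        records = generate_clean(
            kb, SynthConfig(n=5000, seed=3, loinc_codes=("26515-7",)))
        entry = derive_lrr_entry(
            "26515-7", records, {units["preferred_platelet"]: len(records)})
        values = [r.value for r in records]
        assert min(values) <= entry.min_reasonable
        assert entry.max_reasonable <= max(values)
        assert entry.min_reasonable < entry.max_reasonable

    def test_recovers_generator_median(self, kb, units):
        from labharmony.synth import SynthConfig, generate_clean
        records = generate_clean(
            kb, SynthConfig(n=10_000, seed=7, loinc_codes=("2339-0",)))
        entry = derive_lrr_entry(
            "2339-0", records, {units["mg_dL"]: len(records)})
        assert entry.median == pytest.approx(138.8, rel=0.10)
        assert entry.unit == units["mg_dL"]
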