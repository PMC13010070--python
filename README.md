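# labharmony

Knowledge-table-driven correction of LOINC codes and normalization of units
of measure in quantitative laboratory records.

## The problem

Multi-source clinical datasets code laboratory observations with LOINC and
units of measure with SNOMED CT (or UCUM) concept codes, but terminology
binding is error-prone: units arrive missing, synonymous, on the wrong scale
(a `g/dL` that should be `mg/dL`), or incompatible with the assigned LOINC
code (an `fL` volume on a platelet *count* code). Such records are unusable
for aggregation until the code-unit pair is made congruent and the unit is
normalized to a single preferred unit per LOINC code.

`labharmony` implements a system-agnostic, two-step rule engine for this,
driven entirely by three small, shareable knowledge tables — no source data
strings are consulted, only the LOINC code, the unit code, and the numeric
result:

* **LCM** — LOINC conversion map: `(old LOINC, unit) → new LOINC` for
  incongruous pairs where the unit identifies the intended observation.
* **LRR** — laboratory reasonable range map: per LOINC code the preferred
  unit, a plausibility range `[min, max]`, and the median/mean of the
  known-correct value distribution.
* **UMM** — unit multiplier map: `(incorrect unit, correct unit, multiplier
  m, scalar s, type)` rows where `value′ = m·value + s`; the type is
  `nullfill` (absent unit), `synonym`, `unit_conversion`, or `unit_typo`
  (wrong unit label, value already on the correct scale).

Rule precedence per record: (1) a record whose unit already equals the LRR
preferred unit is left untouched (flagged if its value is implausible);
(2) otherwise an LCM row, if one matches, replaces the LOINC code first;
(3) UMM rows then propose unit normalizations; (4) a transformation chain is
accepted only when its end-state value falls inside the target reasonable
range; (5) if several chains survive, the one whose transformed value is
closest to the target median wins (closest to the mean when the median
is 0). Every change is appended to a per-record provenance ledger holding
the rule, a human-readable description, and the changed fields with their
pre-adjustment values — so every harmonization is exactly reversible.

The package also contains the unit error-class taxonomy and before/after
quality metrics (correctness, completeness, per-LOINC threshold counts), a
seeded synthetic-record generator with error injection and known ground
truth, empirical LRR derivation (highest-frequency unit, `[q0.005, q0.995]`
range), FHIR R4 Observation and flat-CSV I/O, and a CLI.

## Worked example

```python
from labharmony import LabRecord, UnitConcept, harmonize_record, revert
from labharmony.examples import demo_knowledge_base

kb = demo_knowledge_base()

# blood glucose coded 2339-0, unit g/dL (SNOMED 258795003), value 0.12:
# either a data-entry error (the value is really mg/dL) or a true g/dL
# needing x1000 conversion. The typo reading gives 0.12 mg/dL — far outside
# the plausible range 40-400 — so the conversion reading wins.
rec = LabRecord("ex1", "2339-0", unit=UnitConcept("258795003", "g/dL"), value=0.12)
res = harmonize_record(rec, kb)
print(res.status, res.record.value, res.record.unit.display)
print(res.record.provenance[0].description)
print(revert(res.record).value)
```

prints

```
transformed 120.0 mg/dL
value converted from g/dL to mg/dL (x 1000)
0.12
```

The record is now a plausible 120 mg/dL glucose; the ledger lets `revert`
restore the original 0.12 g/dL exactly. A platelet count coded 26515-7 with
unit fL instead gets its *LOINC code* corrected (to the entitic-mean-volume
code 28542-9), and a platelet record with a missing unit is null-filled with
the preferred unit only while its value lies within the reasonable range.

The same CLI pipeline:

```sh
labharmony harmonize --lcm lcm.csv --lrr lrr.csv --umm umm.csv \
    --in records.csv --out harmonized.csv --summary summary.json
```

exits nonzero only on structural errors — unresolved records are results,
not failures.

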