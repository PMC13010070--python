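# Methods

## Model

A quantitative laboratory record is the triple (LOINC code, unit concept
code, numeric value), plus identifiers and metadata. The engine assumes the
upstream pipeline has already bound observation strings to LOINC and unit
strings to SNOMED CT (or UCUM) codes; free-text parsing is out of scope, and
matching is performed on concept codes only, never on display strings.
Only finite numeric results are in scope.

Harmonization is a two-step, knowledge-table-driven procedure:

1. **LOINC conversion.** If the (LOINC, unit) pair keys a row of the LOINC
   conversion map (LCM), the unit is taken as evidence of the intended
   observation and the LOINC code is replaced. The LCM is keyed by the
   composite (old LOINC code, unit code); conversion is applied at most once
   per record — the procedure is deliberately two-step, not a fixed-point
   iteration, so chained conversions are not attempted.
2. **Unit normalization.** Against the (possibly updated) LOINC code's
   preferred unit, every unit multiplier map (UMM) row whose incorrect unit
   matches the record's unit (or the null-unit row when the unit is absent)
   and whose correct unit is the preferred unit proposes
   `value′ = m·value + s`. The additive scalar `s` exists only for
   temperature conversions; `nullfill`, `synonym` and `unit_typo` rows must
   have `m = 1, s = 0` (enforced at load).

**Range gating.** A transformation chain is accepted only when its end-state
value lies inside the target LOINC code's reasonable range
`[min_reasonable, max_reasonable]` (inclusive on both ends — the source
ranges are printed without open/closed notation, and inclusivity makes the
boundary cases deterministic). Because ranges are defined only in the
preferred unit, a LOINC conversion is judged after the *full* chain
(conversion plus any unit normalization) completes. If the conversion branch
yields no in-range end state the engine falls back to unit normalization on
the original code; if that fails too, the record is left untouched and
flagged `unresolved`.

**Conflict resolution.** When more than one chain survives the range gate
(typically the prefix-error ambiguity: `g/dL` as a typo for `mg/dL` versus a
true g/dL needing ×1000), the candidate whose transformed value is closest
to the target distribution's median wins; when the median is 0, distance
from the mean is used. Exact distance ties are broken by a fixed
multiplier-type priority — nullfill > synonym > unit_typo > unit_conversion —
preferring value-preserving transforms. The tiebreak is this package's
design choice; the proximity rule itself does not order exact ties.

**Provenance and reversibility.** Every transformation appends a ledger
entry: rule, human-readable description, `changed_fields` (attribute name →
pre-adjustment value, stored verbatim — no rounding anywhere in the engine),
and the reference values used (multiplier, scalar, target range,
median/mean). `revert` replays pre-adjustment values in reverse ledger order
and restores the original LOINC/unit/value exactly, bit for bit.

**Degenerate inputs.** A LOINC code absent from the range table passes
through untouched with flag `unknown_loinc` (status `unresolved`); a
conforming record with an implausible value is flagged
`out_of_range_flagged` but never altered or excluded — exclusion is a
downstream analyst's decision. No data condition raises an exception in the
streaming path.

## Knowledge tables

Integrity is validated at load: unique primary keys per table, positive
multipliers, value-preserving constraints on non-conversion rows,
`min < max` and `min ≤ median ≤ max` per range row (the mean is deliberately
unchecked: curated tables in circulation contain mean/median pairs on
opposite sides, and the engine only consults the mean when the median is 0).
Strict mode additionally requires every LCM target code to have a range
entry — without it a conversion could never be range-gated. The shipped
`examples.core_tables()` tier reproduces the minimal published-style rows
and therefore fails strict validation (its three conversion targets carry no
range rows); `examples.demo_tables()` adds clearly-labeled synthetic range
and multiplier rows to close the references.

Unit concept codes default to SNOMED CT. Because the engine matches codes
only, swapping the tables' unit codes for UCUM (helper `examples.to_ucum`)
requires no engine change; this is asserted by re-running the full
worked-example suite under translated tables.

### Empirical derivation

Range entries are derived from a corpus per LOINC code: the preferred unit
is the highest-frequency observed unit (a tie raises an error — no tiebreak
is defensible without a curator); the range is the `[q0.005, q0.995]`
empirical quantile interval (linear interpolation between order statistics,
type 7), with an optional symmetric padding fraction, default 0, for
implementations that prefer ranges "near" rather than "at" the outer
quantiles. The canonical summary grid is
{0.005, 0.025, 0.16, 0.5, 0.84, 0.975, 0.995}. Note the in-sample coverage
of the inclusive type-7 interval is `1 − 2(⌊0.005(n−1)⌋ + 1)/n`, which
equals 99.0% exactly at round corpus sizes (n = 1,000, 2,000, 10,000); the
tests use such sizes.

## Synthetic data

The generator emulates a multi-source laboratory feed at a per-record level:
values are drawn i.i.d. per LOINC code from a lognormal distribution whose
median is anchored at the range table's median (σ = 0.35 on the log scale,
a typical dispersion for lab analytes), rejection-sampled into
`[min, max]` — a truncated-normal alternative is available for analytes
whose anchor is nonpositive. Corruption kinds mirror the correctable error
patterns: unit synonyms, missing units, scale typos (unit label wrong, value
already on the correct scale), convertible units (value divided by the
table multiplier so conversion restores it), LOINC-incompatible pairs
(record rewritten to a conversion row's old pair), and an unrecoverable
pattern (a unit code absent from every table). Error-kind counts follow the
configured mix exactly via largest-remainder apportionment, and kinds are
assigned only to records whose LOINC code has supporting table rows
(scarcest kinds first); an unsatisfiable quota is a configuration error
naming the gap.

Defaults: the standing mix is 70% clean, 8% missing unit, 6% synonym,
6% convertible, 5% scale typo, 3% LOINC-incompatible, 2% unrecoverable —
clean-dominated with missing units as the leading defect, the qualitative
shape of real multi-source feeds. Recovery studies use `RECOVERABLE_MIX`
(the four reversible patterns at 23% each plus 8% clean) over
`RECOVERY_LOINC_CODES`, which upweights the two codes carrying unit-
multiplier rows. Corruptions for which more than one reading lands in range
(or which collide with a conversion row) are labeled `ambiguous` in the
ground-truth sidecar, since even a perfect engine may legitimately choose
the other reading; they are excluded from the ≥99% recovery criterion.

What the generator does **not** emulate: longitudinal patient structure,
panel/order context, inter-analyte correlation, site-specific unit
dialects beyond the tables, heavy-tailed contamination, or drifting
assay calibrations. Passing tests therefore demonstrate the engine's
logical correctness and reversibility under the cataloged error patterns,
not performance on any particular institution's data.

## Problem sizes and numerics

Property suites run on 10,000-record seeded corpora; derivation tests use
10,000 values per code; the brute-force oracle (independent exhaustive
enumeration of all conversion × normalization chains, scored by the same
proximity rule) is compared record-by-record at the same scale. Value
comparisons in recovery use 1e-9 relative tolerance; reversibility is exact.
All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical configurations are byte-identical.

## Known limitations

* Sample/body-system incongruence is not corrected; only the unit informs
  LOINC conversion.
* Qualitative (non-numeric) results are out of scope.
* One LCM application per record: pathological table cycles are ignored
  rather than resolved.
* The classifier's precedence (synonym before LOINC-suggestive before
  convertible) mirrors the engine's rule order; a unit matching several
  tables is counted once, under the first match.
* Dataset-level correctness/completeness percentages depend entirely on the
  input corpus and table coverage; the package reports them but makes no
  claim about any external dataset.
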