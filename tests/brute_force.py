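"""Independent brute-force oracle for the harmonization engine.

Deliberately naive: enumerates every (optional LOINC conversion) x (unit
multiplier row) chain with plain list scans, keeps range-valid end states,
and scores survivors by the median/mean-proximity rule with the fixed
multiplier-type tiebreak. Shares no code with the engine's chain logic, so
agreement is meaningful.
"""

from __future__ import annotations

_PRIORITY = {"nullfill": 0, "synonym": 1, "unit_typo": 2, "unit_conversion": 3}


def oracle_harmonize(record, kb):
    """Return (status, loinc_code, unit_code or None, value)."""
    unit_code = record.unit.code if record.unit else None

    lrr = None
    for entry in kb.lrr.values():
        if entry.loinc_code == record.loinc_code:
            lrr = entry
    if lrr is None:
        return ("unresolved", record.loinc_code, unit_code, record.value)

    if unit_code is not None and unit_code == lrr.unit.code:
        if lrr.min_reasonable <= record.value <= lrr.max_reasonable:
            return ("conformant", record.loinc_code, unit_code, record.value)
        return ("out_of_range_flagged", record.loinc_code, unit_code,
                record.value)

    def end_states(target_loinc):
        """All range-valid (priority, value, unit_code) end states on one
        target LOINC code."""
        target = None
        for entry in kb.lrr.values():
            if entry.loinc_code == target_loinc:
                target = entry
        if target is None:
            return None, []
        lo, hi = target.min_reasonable, target.max_reasonable
        if unit_code is not None and unit_code == target.unit.code:
            # already the preferred unit: value must merely be plausible
            if lo <= record.value <= hi:
                return target, [(-1, record.value, unit_code)]
            return target, []
        states = []
        for entry in kb.umm.values():
            incorrect = entry.incorrect_unit.code if entry.incorrect_unit else None
            if incorrect == unit_code and entry.correct_unit.code == target.unit.code:
                value = record.value * entry.multiplier + entry.scalar_constant
                if lo <= value <= hi:
                    states.append((_PRIORITY[entry.multiplier_type], value,
                                   target.unit.code))
        return target, states

    def pick(target, states):
        anchor = target.median if target.median != 0 else target.mean
        best = min(states, key=lambda s: (abs(s[1] - anchor), s[0]))
        return ("transformed", target.loinc_code, best[2], best[1])

    # LOINC conversion takes precedence when its completed chain survives
    if unit_code is not None:
        for entry in kb.lcm.values():
            if (entry.old_loinc_code == record.loinc_code
                    and entry.unit_code == unit_code):
                target, states = end_states(entry.new_loinc_code)
                if states:
                    return pick(target, states)

    target, states = end_states(record.loinc_code)
    if states:
        return pick(target, states)
    return ("unresolved", record.loinc_code, unit_code, record.value)
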