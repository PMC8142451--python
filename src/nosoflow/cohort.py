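"""Cohort construction: eligibility rules, timing validation, outlier trim.

The eligibility screen mirrors a retrospective HAI case-control design
in an elderly, non-elective medical population: spells must be
non-elective, aged 65+, at least 48 hours long, under a non-surgical
specialty, free of positive cultures in the first 48 hours
(community-acquired infections), internally consistent in their
timestamps, and complete on the modelled fields.  Rules are applied in
a fixed order and each spell is attributed to the first rule it fails,
which yields the familiar flow-chart attrition log.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

from .config import SURGICAL_TFCS
from .types import ConfigError, ExclusionLog, HAI_THRESHOLD_DAYS, Patient, Spell

#: canonical rule order; a spell is removed by the first rule it fails.
DEFAULT_RULES: tuple[str, ...] = (
    "non_elective",
    "age_ge_65",
    "duration_ge_48h",
    "no_surgical_tfc",
    "no_early_infection",
    "timing_valid",
    "complete_fields",
)

_TIME_TOL = 1e-9


def validate_timing(spell: Spell) -> list[str]:
    """Return inconsistency codes for a spell; an empty list means valid.

    Checks, in order of appearance in the returned list:
    ``discharge_not_after_admission``, ``overlapping_ward_stays``,
    ``gapped_ward_stays``, ``sample_outside_spell``,
    ``episode_outside_spell``.  The validator never raises.
    """
    codes: list[str] = []
    if spell.discharge_time <= spell.admission_time:
        codes.append("discharge_not_after_admission")

    stays = sorted(spell.ward_stays, key=lambda w: w.entry_time)
    overlap = gap = False
    for prev, nxt in zip(stays, stays[1:]):
        if nxt.entry_time < prev.exit_time - _TIME_TOL:
            overlap = True
        elif nxt.entry_time > prev.exit_time + _TIME_TOL:
            gap = True
    if stays and not codes:
        if abs(stays[0].entry_time - spell.admission_time) > _TIME_TOL:
            gap = True
        if abs(stays[-1].exit_time - spell.discharge_time) > _TIME_TOL:
            gap = True
    if any(w.exit_time <= w.entry_time for w in stays):
        overlap = True
    if overlap:
        codes.append("overlapping_ward_stays")
    if gap:
        codes.append("gapped_ward_stays")

    for m in spell.samples:
        if not (spell.admission_time - _TIME_TOL <= m.collection_time <= spell.discharge_time + _TIME_TOL):
            codes.append("sample_outside_spell")
            break
    for e in spell.episodes:
        if e.episode_start < spell.admission_time - _TIME_TOL or e.episode_end > spell.discharge_time + _TIME_TOL:
            codes.append("episode_outside_spell")
            break
    return codes


def dominant_tfc_whole_spell(spell: Spell) -> str | None:
    """TFC with the longest total duration over the full spell."""
    if not spell.episodes:
        return None
    totals: dict[str, float] = {}
    first: dict[str, float] = {}
    for e in spell.episodes:
        totals[e.tfc] = totals.get(e.tfc, 0.0) + e.duration
        first.setdefault(e.tfc, e.episode_start)
    best = max(totals.values())
    tied = [t for t, v in totals.items() if v == best]
    return min(tied, key=lambda t: first[t])


def first_positive_time(spell: Spell) -> float | None:
    times = [m.collection_time for m in spell.samples if m.positive]
    return min(times) if times else None


def _complete(spell: Spell, patient: Patient | None) -> bool:
    if patient is None:
        return False
    scalar_fields = (
        patient.age_at_admission,
        patient.gender,
        spell.hospital_site,
        spell.admission_class,
        spell.discharge_destination,
    )
    if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in scalar_fields):
        return False
    return bool(spell.ward_stays) and bool(spell.episodes)


def _rule_predicates(patients_by_id: dict[str, Patient], surgical_tfcs: Sequence[str]):
    surgical = set(surgical_tfcs)

    def non_elective(sp: Spell) -> bool:
        return sp.admission_class == "non-elective"

    def age_ge_65(sp: Spell) -> bool:
        pat = patients_by_id.get(sp.patient_id)
        return pat is not None and pat.age_at_admission >= 65

    def duration_ge_48h(sp: Spell) -> bool:
        return sp.duration >= HAI_THRESHOLD_DAYS

    def no_surgical_tfc(sp: Spell) -> bool:
        return dominant_tfc_whole_spell(sp) not in surgical

    def no_early_infection(sp: Spell) -> bool:
        t = first_positive_time(sp)
        # strictly inside the first 48 h: a culture at exactly 48 h is
        # hospital-acquired, not grounds for exclusion
        return t is None or t - sp.admission_time >= HAI_THRESHOLD_DAYS

    def timing_valid(sp: Spell) -> bool:
        return not validate_timing(sp)

    def complete_fields(sp: Spell) -> bool:
        return _complete(sp, patients_by_id.get(sp.patient_id))

    return {
        "non_elective": non_elective,
        "age_ge_65": age_ge_65,
        "duration_ge_48h": duration_ge_48h,
        "no_surgical_tfc": no_surgical_tfc,
        "no_early_infection": no_early_infection,
        "timing_valid": timing_valid,
        "complete_fields": complete_fields,
    }


def apply_exclusions(
    spells: Sequence[Spell],
    patients: Iterable[Patient],
    rules: Sequence[str] = DEFAULT_RULES,
    surgical_tfcs: Sequence[str] = SURGICAL_TFCS,
) -> tuple[list[Spell], ExclusionLog]:
    """Apply eligibility rules in order; return included spells and the log.

    Each spell is attributed to the first rule it fails, so the log rows
    sum to the total attrition.  The included set itself does not depend
    on rule order because every rule is a per-spell predicate.
    """
    patients_by_id = {p.patient_id: p for p in patients}
    predicates = _rule_predicates(patients_by_id, surgical_tfcs)
    unknown = [r for r in rules if r not in predicates]
    if unknown:
        raise ConfigError(f"unknown exclusion rules: {unknown}; valid: {sorted(predicates)}")

    log = ExclusionLog()
    log.add("initial", 0, len(spells))
    current = list(spells)
    for rule in rules:
        pred = predicates[rule]
        kept = [sp for sp in current if pred(sp)]
        log.add(rule, len(current) - len(kept), len(kept))
        current = kept
    return current, log


def trim_time_at_risk_outliers(
    records,
    percentile: float = 99.0,
    threshold: float | None = None,
):
    """Drop records whose time at risk lies strictly above a cutoff.

    The cutoff is the empirical ``percentile`` of the ``time_at_risk``
    column (linear-interpolation order statistic), or a fixed absolute
    ``threshold`` when supplied.  Returns ``(trimmed records, cutoff)``.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records to trim outliers")
    if threshold is None:
        if not (0.0 < percentile <= 100.0):
            raise ConfigError("percentile must lie in (0, 100]")
        threshold = float(np.percentile(np.asarray(records["time_at_risk"], dtype=float), percentile))
    kept = records[records["time_at_risk"] <= threshold].copy()
    return kept, float(threshold)
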