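"""Covariate derivation from the event stream, censored at the index time.

Every exposure is computed on the history strictly BEFORE the index
time (the first positive collection for cases, discharge or death for
controls): ward changes, ICU entries and episode starts that fall
exactly on the index do not count, because exposure must precede the
outcome.  Procedure counts for the episode containing the index are
linearly interpolated, assuming procedures are spread evenly over the
episode.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from . import elixhauser
from .types import ConsultantEpisode, OutcomeAssignment, Patient, Spell, WardStay


def time_at_risk(spell: Spell, assignment: OutcomeAssignment) -> float:
    """Days between admission and the index time."""
    t = assignment.index_time - spell.admission_time
    if t < 0:
        raise ValueError(
            f"spell {spell.spell_id}: index time precedes admission ({t:.3f} days)"
        )
    return t


def count_transfers(ward_stays: Sequence[WardStay], index_time: float) -> int:
    """Intrahospital transfers strictly before the index time.

    A transfer is any change of ward ID between consecutive stays,
    irrespective of how long the new location is occupied; consecutive
    stays on the same ward (bed moves) do not count, while a return to
    a previously occupied ward does.
    """
    times = [w.entry_time for w in ward_stays]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("ward stays must be ordered by entry time")
    n = 0
    for prev, nxt in zip(ward_stays, ward_stays[1:]):
        if nxt.ward_id != prev.ward_id and nxt.entry_time < index_time:
            n += 1
    return n


def interpolate_procedures(episodes: Sequence[ConsultantEpisode], index_time: float) -> float:
    """Procedure count up to the index time.

    Episodes that ended on or before the index contribute their full
    OPCS-4 count; the episode containing the index contributes
    ``count * (index - start) / (end - start)``.  At the control limit
    (index = discharge) this is the plain sum over all episodes.
    """
    total = 0.0
    for e in episodes:
        if e.episode_end - e.episode_start <= 0:
            raise ValueError("zero-length consultant episode")
        if e.episode_end <= index_time:
            total += e.opcs4_count
        elif e.episode_start < index_time:
            total += e.opcs4_count * (index_time - e.episode_start) / (e.episode_end - e.episode_start)
    return total


def elixhauser_count(episodes: Sequence[ConsultantEpisode], index_time: float) -> int:
    """Distinct Elixhauser indicators among episodes begun before the index."""
    codes: list[str] = []
    for e in episodes:
        if e.episode_start < index_time:
            codes.extend(e.icd10_codes)
    return elixhauser.count_indicators(codes)


def dominant_tfc(episodes: Sequence[ConsultantEpisode], index_time: float) -> str:
    """TFC with the longest duration before the index; ties -> earliest."""
    totals: dict[str, float] = {}
    first_seen: dict[str, float] = {}
    for e in episodes:
        if e.episode_start >= index_time:
            continue
        truncated = min(e.episode_end, index_time) - e.episode_start
        totals[e.tfc] = totals.get(e.tfc, 0.0) + truncated
        first_seen.setdefault(e.tfc, e.episode_start)
    if not totals:
        raise ValueError("no consultant episode begun before the index time")
    best = max(totals.values())
    tied = [t for t, v in totals.items() if v == best]
    return min(tied, key=lambda t: first_seen[t])


def icu_flag(ward_stays: Sequence[WardStay], index_time: float) -> bool:
    """Whether any ICU stay was entered strictly before the index time."""
    return any(w.is_icu and w.entry_time < index_time for w in ward_stays)


# ----------------------------------------------------------------------
# Banding, mirroring the categories used in the descriptive table

AGE_BANDS = ["65-70", "71-75", "76-80", "81-85", "86+"]
_AGE_EDGES = [65, 71, 76, 81, 86, np.inf]

TIME_BANDS = ["2-5", "5-7", "7-10", "10-15", "15-20", "20-30", "30-40", "40+"]
_TIME_EDGES = [2, 5, 7, 10, 15, 20, 30, 40, np.inf]

ELIX_BANDS = ["0", "1-3", "4-6", "7-9", "10+"]
_ELIX_EDGES = [0, 1, 4, 7, 10, np.inf]

PROC_BANDS = ["0", "1", "2-8", "9-13", "14+"]
_PROC_EDGES = [0, 1, 2, 9, 14, np.inf]


def _band(value: float, edges: list, labels: list[str], name: str) -> str:
    if value < edges[0]:
        raise ValueError(f"{name} value {value} below the lowest band edge {edges[0]}")
    idx = int(np.searchsorted(edges, value, side="right")) - 1
    return labels[idx]


def age_band(age: int) -> str:
    return _band(age, _AGE_EDGES, AGE_BANDS, "age")


def time_at_risk_band(days: float) -> str:
    """Left-closed, right-open bands: 5.0 days falls in '5-7'."""
    return _band(days, _TIME_EDGES, TIME_BANDS, "time_at_risk")


def elixhauser_band(count: int) -> str:
    return _band(count, _ELIX_EDGES, ELIX_BANDS, "elixhauser")


def procedures_band(procedures: float) -> str:
    """Interpolated (fractional) counts are floored before banding."""
    return _band(math.floor(procedures), _PROC_EDGES, PROC_BANDS, "procedures")


#: covariates banded by :func:`bin_covariates`; source column ->
#: (band column, default edges, default labels, floor first?)
BAND_COLUMNS = {
    "age": ("age_band", _AGE_EDGES, AGE_BANDS, False),
    "time_at_risk": ("time_band", _TIME_EDGES, TIME_BANDS, False),
    "elixhauser_count": ("elix_band", _ELIX_EDGES, ELIX_BANDS, False),
    "procedures": ("proc_band", _PROC_EDGES, PROC_BANDS, True),
}


def load_band_config(path) -> dict:
    """Read per-field band overrides from YAML.

    Expected shape::

        time_at_risk:
          edges: [2, 10, 20, .inf]
          labels: ["2-10", "10-20", "20+"]
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    config = {}
    for field, spec in raw.items():
        if field not in BAND_COLUMNS:
            raise KeyError(f"unknown bandable field {field!r}; valid: {list(BAND_COLUMNS)}")
        edges = [float(e) for e in spec["edges"]]
        labels = [str(lab) for lab in spec["labels"]]
        if len(labels) != len(edges) - 1:
            raise ValueError(f"{field}: need one label per interval between edges")
        config[field] = {"edges": edges, "labels": labels}
    return config


def bin_covariates(records: pd.DataFrame, band_config: dict | None = None) -> pd.DataFrame:
    """Append banded versions of the continuous covariates.

    Band columns come back as ordered categoricals so that the first
    band is the reference level in downstream models.  ``band_config``
    (as returned by :func:`load_band_config`) overrides the default
    edges/labels per source field; intervals stay left-closed.
    """
    band_config = band_config or {}
    out = records.copy()
    for source, (target, edges, labels, floor_first) in BAND_COLUMNS.items():
        override = band_config.get(source)
        if override is not None:
            edges, labels = override["edges"], override["labels"]
        values = out[source]
        if floor_first:
            values = np.floor(values.astype(float))
        out[target] = pd.Categorical(
            [_band(v, edges, labels, source) for v in values],
            categories=labels,
            ordered=True,
        )
    return out


# ----------------------------------------------------------------------
def analysis_record(spell: Spell, assignment: OutcomeAssignment, patient: Patient) -> dict:
    """Derive the full covariate row for one classified spell."""
    idx = assignment.index_time
    return {
        "spell_id": spell.spell_id,
        "patient_id": spell.patient_id,
        "status": assignment.status,
        "case": 1 if assignment.is_case else 0,
        "organism": assignment.organism,
        "specimen_site": assignment.specimen_site,
        "time_at_risk": time_at_risk(spell, assignment),
        "n_transfers": count_transfers(spell.ward_stays, idx),
        "elixhauser_count": elixhauser_count(spell.episodes, idx),
        "procedures": interpolate_procedures(spell.episodes, idx),
        "dominant_tfc": dominant_tfc(spell.episodes, idx),
        "icu_before_index": icu_flag(spell.ward_stays, idx),
        "age": patient.age_at_admission,
        "gender": patient.gender,
        "ethnicity": patient.ethnicity,
        "hospital_site": spell.hospital_site,
        "discharge_destination": spell.discharge_destination,
        "died_in_hospital": spell.died_in_hospital,
        "weekend_admission": int(spell.admission_time) % 7 >= 5,
    }


def build_analysis_records(
    spells: Sequence[Spell],
    assignments: Sequence[OutcomeAssignment],
    patients: Sequence[Patient],
) -> pd.DataFrame:
    """One banded covariate row per classified spell.

    ``assignments`` must align with ``spells`` by spell_id (any order).
    """
    by_id = {a.spell_id: a for a in assignments}
    pat_by_id = {p.patient_id: p for p in patients}
    rows = [analysis_record(sp, by_id[sp.spell_id], pat_by_id[sp.patient_id]) for sp in spells]
    records = pd.DataFrame(rows)
    records["gender"] = pd.Categorical(records["gender"], categories=["female", "male"])
    records["hospital_site"] = pd.Categorical(records["hospital_site"], categories=[1, 2, 3])
    tfcs = sorted(records["dominant_tfc"].unique())
    # general medicine first so it serves as the reference specialty
    if "general_medicine" in tfcs:
        tfcs.insert(0, tfcs.pop(tfcs.index("general_medicine")))
    records["dominant_tfc"] = pd.Categorical(records["dominant_tfc"], categories=tfcs)
    records["discharge_destination"] = pd.Categorical(
        records["discharge_destination"],
        categories=["own residence", "nursing home", "other provider", "died"],
    )
    return bin_covariates(records)
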