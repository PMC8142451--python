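"""Outcome classification: case/control status and the index time.

A spell is a case when it carries at least one positive culture; the
index time is the collection time of the FIRST positive sample (later
infections during the same spell are ignored).  Controls take their
discharge-or-death time as the index.  The index time censors every
exposure computed downstream.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import pandas as pd

from .types import ContractViolation, HAI_THRESHOLD_DAYS, MicroSample, OutcomeAssignment, Spell

STERILE_SITES = frozenset({"blood", "urine"})
KNOWN_SITES = frozenset({"blood", "urine", "other"})


def classify_spell(spell: Spell) -> OutcomeAssignment:
    """Assign case/control status and the index time to an eligible spell.

    Expects eligibility screening upstream, so a positive sample in the
    first 48 hours is a contract violation.  Ties on collection time
    keep the first positive in input order (with a warning).
    """
    positives = [m for m in spell.samples if m.positive]
    if not positives:
        return OutcomeAssignment(spell.spell_id, "control", spell.discharge_time)

    earliest = min(positives, key=lambda m: m.collection_time)
    if earliest.collection_time - spell.admission_time < HAI_THRESHOLD_DAYS:
        raise ContractViolation(
            f"spell {spell.spell_id}: positive sample at "
            f"{earliest.collection_time - spell.admission_time:.3f} days after admission; "
            "community-acquired infections must be excluded upstream"
        )
    ties = [m for m in positives if m.collection_time == earliest.collection_time]
    if len(ties) > 1:
        warnings.warn(
            f"spell {spell.spell_id}: {len(ties)} positive samples share the earliest "
            "collection time; keeping the first in input order",
            stacklevel=2,
        )
    first = ties[0]
    return OutcomeAssignment(
        spell.spell_id, "case", first.collection_time, first.organism, first.specimen_site
    )


def is_sterile_site(sample: MicroSample) -> bool:
    """Whether the specimen came from a sterile body site (blood or urine)."""
    site = sample.specimen_site
    if site not in KNOWN_SITES:
        raise ValueError(
            f"unknown specimen site {site!r}; allowed sites: {sorted(KNOWN_SITES)}"
        )
    return site in STERILE_SITES


def organism_table(cases: Sequence[OutcomeAssignment] | pd.Series) -> pd.DataFrame:
    """Ranked organism counts among cases.

    Returns one row per organism with columns ``n``, ``pct`` (share of
    ALL cases, in percent) and ``cumulative_pct``, sorted by descending
    count.  Percentages sum to 100 exactly when every case's organism is
    listed.
    """
    if isinstance(cases, pd.Series):
        organisms = cases
    else:
        organisms = pd.Series([a.organism for a in cases])
    if organisms.empty:
        raise ValueError("organism_table requires at least one case")
    counts = organisms.value_counts()
    table = pd.DataFrame({"organism": counts.index, "n": counts.to_numpy()})
    table["pct"] = 100.0 * table["n"] / len(organisms)
    table["cumulative_pct"] = table["pct"].cumsum()
    return table
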