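"""Sensitivity re-analyses of the transfer-infection association.

Three alternative specifications probe the robustness of the primary
estimate:

* ``index_shift_12h`` / ``index_shift_24h`` — the index time of cases
  is moved 12 or 24 hours before the collection time, guarding against
  transfers triggered by a suspected (not yet confirmed) infection,
  e.g. isolation moves to a side room.  Cases whose shifted time at
  risk falls under 48 hours no longer meet the case definition and are
  removed.  By default ALL covariates are recomputed at the shifted
  index; a flag restricts the shift to the time-at-risk value alone.
* ``surgical_by_opcs`` — surgical spells are identified by operative
  OPCS-4 codes rather than by specialty (TFC), guarding against
  medical patients misclassified under surgical specialties.
* ``sterile_sites_only`` — cases are restricted to isolates from a
  sterile body site (blood or urine), guarding against colonisation
  misclassified as infection.  Non-sterile cases are removed from the
  analysis by default; optionally they can be demoted to controls
  (with covariates re-censored at discharge).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .cohort import DEFAULT_RULES, apply_exclusions, trim_time_at_risk_outliers
from .elixhauser import normalize_code
from .features import build_analysis_records
from .outcomes import STERILE_SITES
from .pipeline import MULTIVARIABLE_TERMS, AnalysisResult, CohortResult, classify_all, fit_multivariable, fit_univariable
from .types import ConfigError, HAI_THRESHOLD_DAYS, OutcomeAssignment, Patient, Spell

SENSITIVITY_NAMES = ("index_shift_12h", "index_shift_24h", "surgical_by_opcs", "sterile_sites_only")

#: operative OPCS-4 codes marking a spell as surgical.  A placeholder
#: default covering the codes the synthetic generator emits; supply the
#: locally appropriate list for real data.
DEFAULT_SURGICAL_OPCS: tuple[str, ...] = ("H019", "T203", "W371", "L189")


@dataclass
class SensitivitySpec:
    name: str
    shift_hours: float | None = None
    opcs_codes: tuple[str, ...] = DEFAULT_SURGICAL_OPCS
    sites: frozenset = field(default_factory=lambda: frozenset(STERILE_SITES))
    nonsterile_as_controls: bool = False
    shift_features: bool = True  # recompute all covariates at the shifted index

    def __post_init__(self) -> None:
        if self.name not in SENSITIVITY_NAMES:
            raise ConfigError(f"unknown sensitivity {self.name!r}; valid: {SENSITIVITY_NAMES}")
        if self.name.startswith("index_shift"):
            expected = 12.0 if self.name.endswith("12h") else 24.0
            if self.shift_hours is None:
                self.shift_hours = expected
            if self.shift_hours not in (12.0, 24.0):
                raise ConfigError("shift hours must be 12 or 24")


def shift_index(
    assignments: Sequence[OutcomeAssignment],
    spells: Sequence[Spell],
    hours: float,
) -> tuple[list[OutcomeAssignment], list[str]]:
    """Move case index times ``hours`` earlier; drop reclassified cases.

    Cases whose shifted time at risk falls below 48 hours no longer
    satisfy the case definition and are removed (their spell ids are
    returned in the second element).  Controls are untouched.
    """
    if hours <= 0:
        raise ValueError("shift hours must be positive")
    adm = {sp.spell_id: sp.admission_time for sp in spells}
    shifted: list[OutcomeAssignment] = []
    dropped: list[str] = []
    for a in assignments:
        if not a.is_case:
            shifted.append(a)
            continue
        new_index = a.index_time - hours / 24.0
        if new_index - adm[a.spell_id] < HAI_THRESHOLD_DAYS:
            dropped.append(a.spell_id)
            continue
        shifted.append(
            OutcomeAssignment(a.spell_id, "case", new_index, a.organism, a.specimen_site)
        )
    return shifted, dropped


def _code_times(episode) -> list[tuple[str, float]]:
    """Implied timestamps of an episode's procedure codes.

    OPCS-4 codes are aggregated per consultant episode without their own
    timestamps; consistent with the even-spread assumption behind the
    procedure interpolation, code ``j`` of ``n`` is placed at
    ``start + (j + 0.5)/n * duration``.
    """
    n = len(episode.opcs4_codes)
    return [
        (code, episode.episode_start + (j + 0.5) / n * episode.duration)
        for j, code in enumerate(episode.opcs4_codes)
    ]


def exclude_surgical_by_opcs(
    spells: Sequence[Spell],
    code_list: Sequence[str],
    assignments: Sequence[OutcomeAssignment] | None = None,
) -> list[Spell]:
    """Remove spells carrying a listed operative code before their index.

    ``code_list`` entries are matched as normalised prefixes.  Without
    ``assignments`` the index defaults to discharge (all codes count).
    """
    if not code_list:
        raise ValueError("surgical OPCS-4 code list must not be empty")
    prefixes = tuple(normalize_code(c) for c in code_list)
    index_by_id = (
        {a.spell_id: a.index_time for a in assignments} if assignments is not None else {}
    )
    kept = []
    for sp in spells:
        index = index_by_id.get(sp.spell_id, sp.discharge_time)
        surgical = any(
            normalize_code(code).startswith(prefixes) and t < index
            for ep in sp.episodes
            for code, t in _code_times(ep)
        )
        if not surgical:
            kept.append(sp)
    return kept


def restrict_sterile(records: pd.DataFrame, sites: frozenset = STERILE_SITES) -> pd.DataFrame:
    """Drop cases whose isolate came from a non-sterile site.

    Removal, not reclassification: such spells leave the analysis
    entirely, controls are unchanged.
    """
    is_case = records["status"] == "case"
    sterile = records["specimen_site"].isin(sites)
    return records[~is_case | sterile].copy()


# ----------------------------------------------------------------------
def run_sensitivity(
    spec: SensitivitySpec,
    patients: Sequence[Patient],
    spells: Sequence[Spell],
    terms: Sequence[str] = MULTIVARIABLE_TERMS,
    trim_percentile: float = 99.0,
) -> AnalysisResult:
    """Re-run the whole pipeline under one alternative specification."""
    rules = list(DEFAULT_RULES)
    if spec.name == "surgical_by_opcs":
        rules.remove("no_surgical_tfc")
    included, log = apply_exclusions(spells, patients, rules=rules)
    assignments = classify_all(included)

    if spec.name.startswith("index_shift"):
        full = dict(zip((a.spell_id for a in assignments), assignments))
        shifted, dropped = shift_index(assignments, included, spec.shift_hours)
        keep = {a.spell_id for a in shifted}
        included = [sp for sp in included if sp.spell_id in keep]
        log.add("index_shift_case_floor", len(dropped), len(included))
        if spec.shift_features:
            assignments = shifted
        else:  # shift only the time-at-risk value; censor covariates as before
            assignments = [full[a.spell_id] for a in shifted]
    elif spec.name == "surgical_by_opcs":
        included = exclude_surgical_by_opcs(included, spec.opcs_codes, assignments)
        keep = {sp.spell_id for sp in included}
        log.add("surgical_opcs", len(assignments) - len(included), len(included))
        assignments = [a for a in assignments if a.spell_id in keep]
    elif spec.name == "sterile_sites_only" and spec.nonsterile_as_controls:
        assignments = [
            a
            if not a.is_case or a.specimen_site in spec.sites
            else OutcomeAssignment(a.spell_id, "control", _discharge(included, a.spell_id))
            for a in assignments
        ]

    records = build_analysis_records(included, assignments, patients)
    if spec.name.startswith("index_shift") and not spec.shift_features:
        from .features import bin_covariates

        records["time_at_risk"] = records["time_at_risk"] - spec.shift_hours / 24.0 * (
            records["status"] == "case"
        )
        records = bin_covariates(records)

    if spec.name == "sterile_sites_only" and not spec.nonsterile_as_controls:
        before = len(records)
        records = restrict_sterile(records, spec.sites)
        keep = set(records["spell_id"])
        included = [sp for sp in included if sp.spell_id in keep]
        assignments = [a for a in assignments if a.spell_id in keep]
        log.add("non_sterile_cases", before - len(records), len(records))

    before = len(records)
    records, threshold = trim_time_at_risk_outliers(records, percentile=trim_percentile)
    log.add("time_at_risk_trim", before - len(records), len(records))
    kept_ids = set(records["spell_id"])
    included = [sp for sp in included if sp.spell_id in kept_ids]
    assignments = [a for a in assignments if a.spell_id in kept_ids]
    cohort = CohortResult(records, log, threshold, list(included), list(assignments))
    return AnalysisResult(
        cohort=cohort,
        univariable=fit_univariable(records),
        multivariable=fit_multivariable(records, terms=terms),
    )


def _discharge(spells: Sequence[Spell], spell_id: str) -> float:
    for sp in spells:
        if sp.spell_id == spell_id:
            return sp.discharge_time
    raise KeyError(spell_id)
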