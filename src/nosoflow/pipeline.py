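"""End-to-end analysis pipeline.

Chains the stages: eligibility exclusions -> case/control
classification -> covariate derivation censored at the index time ->
top-percentile time-at-risk trim -> logistic modelling.  The module
exists so that the primary analysis and each sensitivity re-run share
one code path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .cohort import DEFAULT_RULES, apply_exclusions, trim_time_at_risk_outliers
from .config import SURGICAL_TFCS, GeneratorConfig
from .features import build_analysis_records
from .inference import fit_logistic
from .outcomes import classify_spell
from .synthetic import generate_cohort
from .types import ExclusionLog, ModelResult, OutcomeAssignment, Patient, Spell

#: adjusted-model terms: continuous transfer exposure plus the banded
#: confounder set (age, gender, time at risk, comorbidity burden,
#: admission site, dominant specialty, ICU exposure, procedures,
#: discharge destination).
MULTIVARIABLE_TERMS: tuple[str, ...] = (
    "n_transfers",
    "age_band",
    "gender",
    "time_band",
    "elix_band",
    "hospital_site",
    "dominant_tfc",
    "icu_before_index",
    "proc_band",
    "discharge_destination",
)

UNIVARIABLE_TERMS: tuple[str, ...] = ("n_transfers",)


def classify_all(spells: Sequence[Spell]) -> list[OutcomeAssignment]:
    return [classify_spell(sp) for sp in spells]


@dataclass
class CohortResult:
    """Included analysis records plus the attrition bookkeeping."""

    records: pd.DataFrame
    exclusion_log: ExclusionLog
    trim_threshold: float
    spells: list[Spell]
    assignments: list[OutcomeAssignment]


def build_cohort(
    patients: Sequence[Patient],
    spells: Sequence[Spell],
    rules: Sequence[str] = DEFAULT_RULES,
    surgical_tfcs: Sequence[str] = SURGICAL_TFCS,
    trim_percentile: float | None = 99.0,
    trim_threshold: float | None = None,
) -> CohortResult:
    """Run exclusions, classify outcomes and derive banded covariates."""
    included, log = apply_exclusions(spells, patients, rules=rules, surgical_tfcs=surgical_tfcs)
    assignments = classify_all(included)
    records = build_analysis_records(included, assignments, patients)
    threshold = float("inf")
    if trim_percentile is not None or trim_threshold is not None:
        records, threshold = trim_time_at_risk_outliers(
            records, percentile=trim_percentile if trim_percentile is not None else 99.0,
            threshold=trim_threshold,
        )
        log.add("time_at_risk_trim", len(included) - len(records), len(records))
        kept_ids = set(records["spell_id"])
        included = [sp for sp in included if sp.spell_id in kept_ids]
        assignments = [a for a in assignments if a.spell_id in kept_ids]
    return CohortResult(records, log, threshold, list(included), assignments)


def fit_multivariable(records: pd.DataFrame, terms: Sequence[str] = MULTIVARIABLE_TERMS) -> ModelResult:
    return fit_logistic(records, outcome="case", terms=terms)


def fit_univariable(records: pd.DataFrame) -> ModelResult:
    return fit_logistic(records, outcome="case", terms=UNIVARIABLE_TERMS)


@dataclass
class AnalysisResult:
    cohort: CohortResult
    univariable: ModelResult
    multivariable: ModelResult

    @property
    def transfer_or(self) -> float:
        """Adjusted per-transfer odds ratio."""
        return float(self.multivariable.term("n_transfers").odds_ratio)


def run_analysis(
    patients: Sequence[Patient],
    spells: Sequence[Spell],
    terms: Sequence[str] = MULTIVARIABLE_TERMS,
    **cohort_kwargs,
) -> AnalysisResult:
    cohort = build_cohort(patients, spells, **cohort_kwargs)
    return AnalysisResult(
        cohort=cohort,
        univariable=fit_univariable(cohort.records),
        multivariable=fit_multivariable(cohort.records, terms=terms),
    )


def end_to_end(config: GeneratorConfig, terms: Sequence[str] = MULTIVARIABLE_TERMS) -> AnalysisResult:
    """Generate a synthetic cohort and run the full primary analysis."""
    patients, spells = generate_cohort(config)
    return run_analysis(patients, spells, terms=terms)
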