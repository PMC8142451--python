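"""Core domain types for the hospital-spell event model.

All timestamps are fractional days on a single global clock (day 0 =
start of the observation window).  Spell-relative quantities such as
time at risk are derived on demand by subtracting the admission time.
Ward stays and consultant episodes are half-open intervals
``[start, end)`` that tile the spell interval exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


class ConfigError(ValueError):
    """Raised for invalid generator or pipeline configuration."""


class ContractViolation(RuntimeError):
    """Raised when a stage receives input that an upstream stage should
    have filtered (e.g. a positive culture before 48 hours reaching the
    outcome classifier)."""


#: Hours after admission before which a positive culture is considered
#: community-acquired; expressed in fractional days.
HAI_THRESHOLD_DAYS = 2.0


@dataclass(slots=True)
class Patient:
    patient_id: str
    age_at_admission: int
    gender: str  # "male" | "female"
    ethnicity: str


@dataclass(slots=True)
class WardStay:
    ward_id: str
    entry_time: float
    exit_time: float
    is_icu: bool = False

    @property
    def duration(self) -> float:
        return self.exit_time - self.entry_time


@dataclass(slots=True)
class ConsultantEpisode:
    episode_start: float
    episode_end: float
    tfc: str
    icd10_codes: list[str] = field(default_factory=list)
    opcs4_count: int = 0
    # Individual procedure codes; optional detail used by the OPCS-based
    # surgical sensitivity analysis.  When present, len == opcs4_count.
    opcs4_codes: list[str] = field(default_factory=list)

    @property
    def duration(self) -> float:
        return self.episode_end - self.episode_start


@dataclass(slots=True)
class MicroSample:
    collection_time: float
    organism: Optional[str]
    specimen_site: Optional[str]  # "blood" | "urine" | "other"
    positive: bool


@dataclass(slots=True)
class Spell:
    spell_id: str
    patient_id: str
    hospital_site: int
    admission_time: float
    discharge_time: float
    admission_class: str  # "elective" | "non-elective"
    discharge_destination: str
    died_in_hospital: bool
    ward_stays: list[WardStay] = field(default_factory=list)
    episodes: list[ConsultantEpisode] = field(default_factory=list)
    samples: list[MicroSample] = field(default_factory=list)

    @property
    def duration(self) -> float:
        """Spell length in fractional days."""
        return self.discharge_time - self.admission_time


@dataclass(slots=True)
class OutcomeAssignment:
    """Case/control status and the index time that censors all exposures.

    ``index_time`` is the first positive collection time for cases and
    the discharge (or death) time for controls.
    """

    spell_id: str
    status: str  # "case" | "control"
    index_time: float
    organism: Optional[str] = None
    specimen_site: Optional[str] = None

    @property
    def is_case(self) -> bool:
        return self.status == "case"


@dataclass(slots=True)
class ExclusionLog:
    """Flow-chart style attrition record: one row per eligibility rule."""

    rows: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, rule: str, removed: int, remaining: int) -> None:
        if self.rows and remaining > self.rows[-1][2]:
            raise ValueError("remaining counts must be non-increasing")
        self.rows.append((rule, removed, remaining))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rows, columns=["rule", "removed", "remaining"])


@dataclass(slots=True)
class ModelResult:
    """Fitted logistic model: one row per design-matrix term.

    ``table`` columns: term, coef, se, odds_ratio, ci_low, ci_high, p.
    """

    table: "object"  # pandas.DataFrame
    n: int
    loglik: float
    terms: list[str]

    def term(self, name: str):
        """Return the row (as a Series) for a named term."""
        hit = self.table[self.table["term"] == name]
        if hit.empty:
            raise KeyError(f"no term named {name!r}; have {list(self.table['term'])}")
        return hit.iloc[0]

    def to_dict(self) -> dict:
        return {
            "terms": [
                {
                    "name": r.term,
                    "coef": r.coef,
                    "se": r.se,
                    "or": r.odds_ratio,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "p": r.p,
                }
                for r in self.table.itertuples()
            ],
            "n": self.n,
            "loglik": self.loglik,
        }


@dataclass(slots=True)
class IccResult:
    cluster: str
    between_variance: float
    icc: float
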