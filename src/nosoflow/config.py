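"""Configuration for the synthetic hospital-EHR generator.

Defaults are calibrated to the marginal distributions of the study
population the pipeline is designed for: non-elective medical spells of
patients aged 65+ in a three-site urban hospital network.  In
particular the transfer-count mixture defaults to
(0.278, 0.442, 0.171, 0.110) over 0/1/2/3+ intrahospital transfers, the
length-of-stay law has median ~6.3 days, and the per-day infection
hazard scale yields roughly a 12% hospital-acquired-infection rate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .types import ConfigError

#: 20 treatment function code (TFC) groups; weights follow the reported
#: specialty case-mix (general medicine 31.5%, geriatric 15.1%, ...),
#: with the remainder spread over the minor specialties.  The last four
#: are surgical and appear only on ineligible decoy spells by default.
TFC_LABELS: tuple[str, ...] = (
    "general_medicine",
    "geriatric_medicine",
    "respiratory_medicine",
    "cardiology",
    "stroke_medicine",
    "nephrology",
    "gastroenterology",
    "endocrinology",
    "neurology",
    "medical_oncology",
    "haematology",
    "rheumatology",
    "dermatology",
    "infectious_diseases",
    "palliative_medicine",
    "rehabilitation",
    "general_surgery",
    "trauma_orthopaedics",
    "urology",
    "vascular_surgery",
)

SURGICAL_TFCS: tuple[str, ...] = (
    "general_surgery",
    "trauma_orthopaedics",
    "urology",
    "vascular_surgery",
)

_MINOR_TFC_WEIGHT = (1.0 - (0.315 + 0.151 + 0.089 + 0.084 + 0.081 + 0.052)) / 10

DEFAULT_TFC_MIXTURE: dict[str, float] = {
    "general_medicine": 0.315,
    "geriatric_medicine": 0.151,
    "respiratory_medicine": 0.089,
    "cardiology": 0.084,
    "stroke_medicine": 0.081,
    "nephrology": 0.052,
    **{label: _MINOR_TFC_WEIGHT for label in TFC_LABELS[6:16]},
    # surgical TFCs get zero weight among eligible spells; decoys draw
    # from SURGICAL_TFCS directly.
    **{label: 0.0 for label in SURGICAL_TFCS},
}

#: organism mixture among positive cultures: the nine most common
#: nosocomial isolates at their observed shares of cases, remainder
#: pooled as "Other organism".
DEFAULT_ORGANISM_MIXTURE: dict[str, float] = {
    "Clostridium difficile toxin": 930 / 2877,
    "Escherichia coli": 462 / 2877,
    "Pseudomonas aeruginosa": 250 / 2877,
    "Enterococcus sp": 162 / 2877,
    "Klebsiella pneumoniae": 153 / 2877,
    "Staphylococcus aureus": 135 / 2877,
    "Coliform sp": 99 / 2877,
    "MRSA": 73 / 2877,
    "Coagulase-negative staphylococcus": 67 / 2877,
    "Other organism": 546 / 2877,
}

DEFAULT_AGE_BAND_MIXTURE: dict[str, float] = {
    "65-70": 0.1955,
    "71-75": 0.1714,
    "76-80": 0.1948,
    "81-85": 0.1863,
    "86+": 0.2520,  # printed shares sum to 99.99; rounding absorbed here
}

DEFAULT_PROCEDURE_BAND_MIXTURE: dict[str, float] = {
    "0": 0.3245,
    "1": 0.0765,
    "2-8": 0.4916,
    "9-13": 0.0758,
    "14+": 0.0316,
}

DEFAULT_SITE_MIXTURE: dict[int, float] = {1: 0.3178, 2: 0.5094, 3: 0.1728}

DEFAULT_DESTINATION_MIXTURE: dict[str, float] = {
    "own residence": 0.63,
    "nursing home": 0.16,
    "other provider": 0.138,
    "died": 0.072,
}

DEFAULT_ETHNICITY_MIXTURE: dict[str, float] = {
    "white": 0.60,
    "asian": 0.15,
    "black": 0.12,
    "mixed": 0.04,
    "other": 0.09,
}


def _check_probability_vector(name: str, probs) -> None:
    vals = list(probs)
    if any(p < 0 for p in vals):
        raise ConfigError(f"{name}: probabilities must be non-negative")
    total = sum(vals)
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"{name}: probabilities sum to {total!r}, expected 1")


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic-cohort generator.

    Parameters
    ----------
    n_spells
        Number of hospital spells to generate.
    seed
        Seed for the generator's random stream; identical
        (config, seed) pairs produce bit-identical output.
    beta_transfer
        Log-odds increment of the per-day infection hazard per
        intrahospital transfer accumulated before the candidate
        collection time.  The causal effect the pipeline should recover.
    beta_covariates
        Log-odds effects of non-exposure covariates on the hazard.
        Recognised keys: ``elixhauser`` (per indicator, centred at the
        population mean), ``icu`` (ICU stay entered before the candidate
        time), ``age`` (per year, centred at 79).
    transfer_mixture
        Probability vector over total transfer counts 0, 1, 2, 3+.
    baseline_hazard
        Per-day infection probability for a reference patient
        (no transfers, covariates at their centring values).
    los_median_days, los_sigma
        Eligible length of stay is ``2 + LogNormal(log(median-2), sigma)``
        days: right-skewed, supported above the 48-hour eligibility
        floor, median ``los_median_days``.
    sterile_site_fraction
        Probability that a positive sample is from a sterile site
        (blood or urine).
    decoy_fraction
        Fraction of spells deliberately failing one eligibility rule
        (elective admission, age < 65, stay < 48 h, surgical TFC, or
        infection in the first 48 h) so exclusion logic is exercisable.
    """

    n_spells: int = 25_000
    seed: int = 0
    beta_transfer: float = 0.0
    beta_covariates: dict[str, float] = field(
        default_factory=lambda: {"elixhauser": 0.13, "icu": 1.2, "age": 0.008}
    )
    # printed shares 27.8/44.2/17.1/11.0 sum to 100.1 from rounding;
    # renormalised so the vector is a probability distribution
    transfer_mixture: tuple[float, float, float, float] = (
        0.278 / 1.001,
        0.442 / 1.001,
        0.171 / 1.001,
        0.110 / 1.001,
    )
    tfc_mixture: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TFC_MIXTURE))
    baseline_hazard: float = 0.0145
    #: ward moves cluster shortly after admission (assessment-unit to
    #: destination-ward flow): transfer offsets are exponential with
    #: this mean, truncated at discharge.
    transfer_timescale_days: float = 0.75
    los_median_days: float = 6.3
    los_sigma: float = 1.2
    sterile_site_fraction: float = 0.55
    decoy_fraction: float = 0.20
    icu_probability: float = 0.025
    elixhauser_mean: float = 3.54
    negative_sample_rate: float = 0.25
    organism_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ORGANISM_MIXTURE)
    )
    age_band_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AGE_BAND_MIXTURE)
    )
    procedure_band_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROCEDURE_BAND_MIXTURE)
    )
    site_mixture: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_SITE_MIXTURE))
    destination_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DESTINATION_MIXTURE)
    )
    ethnicity_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ETHNICITY_MIXTURE)
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_spells < 1:
            raise ConfigError("n_spells must be >= 1")
        if not (0.0 <= self.baseline_hazard < 1.0):
            raise ConfigError("baseline_hazard must lie in [0, 1)")
        if len(self.transfer_mixture) != 4:
            raise ConfigError("transfer_mixture must cover counts 0, 1, 2, 3+")
        _check_probability_vector("transfer_mixture", self.transfer_mixture)
        for name in (
            "tfc_mixture",
            "organism_mixture",
            "age_band_mixture",
            "procedure_band_mixture",
            "site_mixture",
            "destination_mixture",
            "ethnicity_mixture",
        ):
            _check_probability_vector(name, getattr(self, name).values())
        if not (0.0 <= self.decoy_fraction < 1.0):
            raise ConfigError("decoy_fraction must lie in [0, 1)")
        if not (0.0 <= self.sterile_site_fraction <= 1.0):
            raise ConfigError("sterile_site_fraction must lie in [0, 1]")
        if self.los_median_days <= 2.0:
            raise ConfigError("los_median_days must exceed the 2-day eligibility floor")

    # ------------------------------------------------------------------
    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["transfer_mixture"] = list(self.transfer_mixture)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "transfer_mixture" in d:
            d["transfer_mixture"] = tuple(d["transfer_mixture"])
        if "site_mixture" in d:
            d["site_mixture"] = {int(k): v for k, v in d["site_mixture"].items()}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
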