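import numpy as np
import pytest

from nosoflow import (
    ConsultantEpisode,
    GeneratorConfig,
    MicroSample,
    Patient,
    Spell,
    WardStay,
    generate_cohort,
)


def make_spell(
    spell_id="S1",
    patient_id="P1",
    admission=0.0,
    discharge=10.0,
    wards=None,
    episodes=None,
    samples=None,
    admission_class="non-elective",
    destination="own residence",
    site=1,
):
    """Hand-build a spell; ``wards`` is a list of (ward_id, entry, exit[, icu]),
    ``episodes`` of (start, end, tfc[, icd10_codes[, opcs4_count]])."""
    sp = Spell(
        spell_id=spell_id,
        patient_id=patient_id,
        hospital_site=site,
        admission_time=admission,
        discharge_time=discharge,
        admission_class=admission_class,
        discharge_destination=destination,
        died_in_hospital=destination == "died",
    )
    for w in wards if wards is not None else [("A", admission, discharge)]:
        sp.ward_stays.append(WardStay(w[0], w[1], w[2], bool(w[3]) if len(w) > 3 else False))
    for e in episodes if episodes is not None else [(admission, discharge, "general_medicine")]:
        codes = list(e[3]) if len(e) > 3 else []
        count = e[4] if len(e) > 4 else 0
        sp.episodes.append(ConsultantEpisode(e[0], e[1], e[2], codes, count))
    for m in samples or []:
        sp.samples.append(MicroSample(m[0], m[1], m[2], m[3]))
    return sp


def make_patient(patient_id="P1", age=80, gender="female", ethnicity="white"):
    return Patient(patient_id, age, gender, ethnicity)


@pytest.fixture(scope="session")
def medium_cohort():
    """A 12 000-spell synthetic cohort with a strong known transfer effect.

    Large enough that every covariate band keeps both cases and controls
    under the sensitivity restrictions."""
    config = GeneratorConfig(n_spells=12000, seed=11, beta_transfer=np.log(1.2))
    patients, spells = generate_cohort(config)
    return config, patients, spells
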