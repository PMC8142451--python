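"""Synthetic hospital-EHR generator.

Emits a relational patient -> spell -> {ward stays, consultant episodes,
microbiology samples} object graph with the statistical structure the
case-control pipeline assumes, and a known, configurable causal effect
of intrahospital transfers on infection so the full pipeline supports
parameter-recovery testing.

Infection mechanism
-------------------
The ward-stay / episode trajectory of a spell is generated first and is
unaffected by infection.  Infection is then drawn day by day over the
at-risk window (48 h after admission to discharge): for each risk day a
candidate collection time ``s`` is drawn uniformly within the day and
the infection fires with probability

    expit( logit(baseline_hazard)
           + beta_transfer * transfers_before(s)
           + beta_elixhauser * (elixhauser - mean)
           + beta_icu * icu_before(s)
           + beta_age * (age - 79) )

The first success places a positive microbiology sample at ``s``.  All
covariates entering the hazard are evaluated on the history strictly
before ``s``, so exposure precedes outcome by construction and the
per-transfer log-odds the downstream logistic model estimates is the
configured ``beta_transfer``.

A configurable fraction of spells are ineligible "decoys" (elective,
under-65, under-48-hours, surgical specialty, or infected within 48 h)
so that cohort-exclusion logic is exercisable on generated data.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import SURGICAL_TFCS, GeneratorConfig
from .elixhauser import INDICATOR_NAMES, REPRESENTATIVE_CODES
from .types import ConsultantEpisode, MicroSample, Patient, Spell, WardStay

_DECOY_TYPES = ("elective", "age_lt_65", "short_stay", "surgical_tfc", "early_infection")

#: minor/diagnostic procedure codes emitted on ordinary medical spells.
_BENIGN_OPCS = ("U051", "U212", "X292", "X403", "Y981", "G459", "E492", "X998")
#: operative codes used to tag surgical activity for the OPCS-based
#: sensitivity analysis.
SURGICAL_OPCS_CODES = ("H019", "T203", "W371", "L189")

_AGE_BAND_RANGES = {
    "65-70": (65, 70),
    "71-75": (71, 75),
    "76-80": (76, 80),
    "81-85": (81, 85),
    "86+": (86, 100),
}

_PROC_BAND_RANGES = {"0": (0, 0), "1": (1, 1), "2-8": (2, 8), "9-13": (9, 13), "14+": (14, 25)}


def _draw_categorical(rng: np.random.Generator, mixture: dict) -> object:
    keys = list(mixture)
    probs = np.asarray(list(mixture.values()), dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def _transfers_before(transfer_times: np.ndarray, t: float) -> int:
    """Ward-change count strictly before time ``t``."""
    return int(np.searchsorted(transfer_times, t, side="left"))


def generate_cohort(config: GeneratorConfig) -> tuple[list[Patient], list[Spell]]:
    """Generate ``config.n_spells`` hospital spells and their patients.

    Returns the object graph; use :func:`write_tables` to serialise it
    to the five-table CSV schema.  Identical configs (including the
    seed) produce bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_spells

    betas = config.beta_covariates
    b_elix = betas.get("elixhauser", 0.0)
    b_icu = betas.get("icu", 0.0)
    b_age = betas.get("age", 0.0)
    b_transfer = config.beta_transfer
    eta0 = logit(config.baseline_hazard) if config.baseline_hazard > 0 else -np.inf

    def _keys_probs(mixture):
        keys = list(mixture)
        probs = np.asarray(list(mixture.values()), dtype=float)
        return keys, probs / probs.sum()

    tfc_labels, tfc_probs = _keys_probs(config.tfc_mixture)
    site_keys, site_probs = _keys_probs(config.site_mixture)
    dest_keys, dest_probs = _keys_probs(config.destination_mixture)
    eth_keys, eth_probs = _keys_probs(config.ethnicity_mixture)
    age_keys, age_probs = _keys_probs(config.age_band_mixture)
    proc_keys, proc_probs = _keys_probs(config.procedure_band_mixture)
    org_keys, org_probs = _keys_probs(config.organism_mixture)
    org_cum = np.cumsum(org_probs)
    tfc_cum = np.cumsum(tfc_probs)
    site_cum = np.cumsum(site_probs)
    dest_cum = np.cumsum(dest_probs)
    age_ranges = np.array([_AGE_BAND_RANGES[k] for k in age_keys])
    proc_ranges = np.array([_PROC_BAND_RANGES[k] for k in proc_keys])

    # vectorised scalar draws, one array per quantity (hot path: a pure
    # Python loop with per-spell rng calls is several times slower)
    decoy_arr = np.full(n, -1)
    decoy_mask = rng.random(n) < config.decoy_fraction
    decoy_arr[decoy_mask] = rng.integers(0, len(_DECOY_TYPES), int(decoy_mask.sum()))
    reuse_u = rng.random(n)
    reuse_pick = rng.random(n)
    age_band_idx = rng.choice(len(age_keys), n, p=age_probs)
    age_u = rng.random(n)
    young_age = rng.integers(30, 65, n)
    gender_u = rng.random(n)
    eth_idx = rng.choice(len(eth_keys), n, p=eth_probs)
    admission_arr = rng.uniform(0.0, 1095.0, n)
    los_long = 2.0 + rng.lognormal(np.log(config.los_median_days - 2.0), config.los_sigma, n)
    los_short = rng.uniform(0.25, 1.99, n)
    m_base = rng.choice(4, n, p=np.asarray(config.transfer_mixture))
    m_extra = rng.geometric(0.6, n) - 1
    icu_mask = rng.random(n) < config.icu_probability
    nep_arr = rng.choice(3, n, p=[0.5, 0.35, 0.15]) + 1
    elix_arr = rng.binomial(31, config.elixhauser_mean / 31, n)
    proc_band_idx = rng.choice(len(proc_keys), n, p=proc_probs)
    proc_u = rng.random(n)
    surg_u = rng.random(n)
    neg_mask = rng.random(n) < config.negative_sample_rate
    neg_frac = rng.random(n)
    early_offset = rng.uniform(0.2, 1.9, n)

    scale = config.transfer_timescale_days
    patients: list[Patient] = []
    spells: list[Spell] = []
    reusable: list[Patient] = []  # eligible-age patients open to repeat spells

    for i in range(n):
        decoy = _DECOY_TYPES[decoy_arr[i]] if decoy_arr[i] >= 0 else None

        # ---- patient ------------------------------------------------
        if decoy != "age_lt_65" and reusable and reuse_u[i] < 0.25:
            patient = reusable[int(reuse_pick[i] * len(reusable))]
        else:
            if decoy == "age_lt_65":
                age = int(young_age[i])
            else:
                lo, hi = age_ranges[age_band_idx[i]]
                age = int(lo + age_u[i] * (hi - lo + 1))
            patient = Patient(
                patient_id=f"P{len(patients):06d}",
                age_at_admission=age,
                gender="male" if gender_u[i] < 0.4964 else "female",
                ethnicity=eth_keys[eth_idx[i]],
            )
            patients.append(patient)
            if decoy != "age_lt_65":
                reusable.append(patient)

        # ---- spell frame --------------------------------------------
        admission = float(admission_arr[i])
        los = float(los_short[i]) if decoy == "short_stay" else float(los_long[i])
        discharge = admission + los
        site = site_keys[int(np.searchsorted(site_cum, rng.random()))]
        destination = dest_keys[int(np.searchsorted(dest_cum, rng.random()))]

        spell = Spell(
            spell_id=f"S{i:06d}",
            patient_id=patient.patient_id,
            hospital_site=site,
            admission_time=admission,
            discharge_time=discharge,
            admission_class="elective" if decoy == "elective" else "non-elective",
            discharge_destination=destination,
            died_in_hospital=destination == "died",
        )

        # ---- ward stays / transfers ---------------------------------
        n_transfers = int(m_base[i])
        if n_transfers == 3:
            n_transfers += int(m_extra[i])
        if n_transfers > 0:
            # front-loaded ward moves: exponential offsets truncated at
            # discharge, so most transfers precede the at-risk window
            u = rng.random(n_transfers)
            offsets = -scale * np.log1p(-u * (1.0 - np.exp(-los / scale)))
            cuts = admission + np.sort(np.clip(offsets, 1e-6, los - 1e-6))
        else:
            cuts = _EMPTY
        icu_idx = int(rng.integers(n_transfers + 1)) if icu_mask[i] else -1
        ward_r = rng.integers(0, 20, n_transfers + 1)
        prev_r = -1
        t0 = admission
        for j in range(n_transfers + 1):
            t1 = float(cuts[j]) if j < n_transfers else discharge
            if j == icu_idx:
                wid = f"ICU-{site}"
                prev_r = -1
            else:
                r = int(ward_r[j])
                if r == prev_r:  # deterministic remap avoids a reject loop
                    r = (r + 7) % 20
                wid = f"W{site}-{r + 1:02d}"
                prev_r = r
            spell.ward_stays.append(WardStay(wid, t0, t1, j == icu_idx))
            t0 = t1
        transfer_times = cuts  # every ward-id change, by construction
        icu_entry = spell.ward_stays[icu_idx].entry_time if icu_idx >= 0 else np.inf

        # ---- consultant episodes ------------------------------------
        n_ep = int(nep_arr[i])
        ep_cuts = np.sort(rng.uniform(admission + 0.05, discharge - 0.05, n_ep - 1))
        ep_bounds = np.concatenate(([admission], ep_cuts, [discharge]))
        if decoy == "surgical_tfc":
            primary_tfc = SURGICAL_TFCS[rng.integers(len(SURGICAL_TFCS))]
        else:
            primary_tfc = tfc_labels[int(np.searchsorted(tfc_cum, rng.random()))]
        for j in range(n_ep):
            if j == 0 or decoy == "surgical_tfc" or rng.random() < 0.7:
                tfc = primary_tfc
            else:
                tfc = tfc_labels[int(np.searchsorted(tfc_cum, rng.random()))]
            spell.episodes.append(
                ConsultantEpisode(float(ep_bounds[j]), float(ep_bounds[j + 1]), tfc)
            )

        # ---- comorbidities: one representative code per indicator ---
        k_elix = int(elix_arr[i])
        if k_elix:
            groups = rng.permutation(31)[:k_elix]
            spell.episodes[0].icd10_codes = [
                REPRESENTATIVE_CODES[INDICATOR_NAMES[g]] for g in sorted(groups)
            ]

        # ---- procedures ---------------------------------------------
        lo, hi = proc_ranges[proc_band_idx[i]]
        total_procs = int(lo + proc_u[i] * (hi - lo + 1))
        durations = np.diff(ep_bounds)
        if n_ep > 1:
            alloc = rng.multinomial(total_procs, durations / durations.sum())
        else:
            alloc = [total_procs]
        # operative codes track, but do not perfectly mirror, surgical
        # specialty: ~10% of surgical-specialty spells carry no operative
        # code and ~3% of medical spells carry one (coding slippage is
        # what the OPCS-based surgical sensitivity analysis probes)
        surgical_spell = surg_u[i] < (0.9 if decoy == "surgical_tfc" else 0.03)
        for ep, cnt in zip(spell.episodes, alloc):
            cnt = int(cnt)
            if cnt:
                ep.opcs4_codes = [_BENIGN_OPCS[r] for r in rng.integers(0, len(_BENIGN_OPCS), cnt)]
            ep.opcs4_count = cnt
        if surgical_spell:
            ep = spell.episodes[0]
            ep.opcs4_codes.insert(0, SURGICAL_OPCS_CODES[rng.integers(len(SURGICAL_OPCS_CODES))])
            ep.opcs4_count += 1

        # ---- infection ----------------------------------------------
        infected_at = None
        if decoy == "early_infection" and config.baseline_hazard > 0:
            # community-acquired decoy; suppressed in the zero-hazard limit
            infected_at = admission + float(early_offset[i])
        elif config.baseline_hazard > 0 and los > 2.0:
            base_eta = eta0 + b_elix * (k_elix - config.elixhauser_mean) + b_age * (
                patient.age_at_admission - 79.0
            )
            start = admission + 2.0
            n_days = int(np.ceil(los - 2.0))
            offsets = rng.random(n_days)
            draws = rng.random(n_days)
            varying = (transfer_times.size and transfer_times[-1] >= start) or (
                start < icu_entry < discharge
            )
            if not varying:
                # hazard constant over the at-risk window (common case:
                # transfers and ICU entry precede 48 h)
                p = expit(
                    base_eta
                    + b_transfer * len(transfer_times)
                    + b_icu * (icu_entry < start)
                )
                for d in np.flatnonzero(draws < p):
                    s = start + d + offsets[d]
                    if s < discharge:
                        infected_at = s
                        break
            else:
                for d in range(n_days):
                    s = start + d + offsets[d]
                    if s >= discharge:
                        continue
                    eta = (
                        base_eta
                        + b_transfer * _transfers_before(transfer_times, s)
                        + b_icu * (icu_entry < s)
                    )
                    if draws[d] < expit(eta):
                        infected_at = s
                        break

        if infected_at is not None:
            organism = org_keys[int(np.searchsorted(org_cum, rng.random()))]
            if rng.random() < config.sterile_site_fraction:
                site_label = "blood" if rng.random() < 0.45 else "urine"
            else:
                site_label = "other"
            spell.samples.append(MicroSample(infected_at, organism, site_label, True))
        if neg_mask[i]:
            spell.samples.append(
                MicroSample(admission + float(neg_frac[i]) * los, None, "other", False)
            )
        spell.samples.sort(key=lambda s: s.collection_time)

        spells.append(spell)

    return patients, spells


_EMPTY = np.empty(0)


# ----------------------------------------------------------------------
def count_spell_transfers(spell: Spell, before: float | None = None) -> int:
    """Ward-ID changes over the whole spell (or strictly before ``before``)."""
    stays = spell.ward_stays
    n = 0
    for prev, nxt in zip(stays, stays[1:]):
        if nxt.ward_id != prev.ward_id and (before is None or nxt.entry_time < before):
            n += 1
    return n


def summarize_marginals(
    spells: Sequence[Spell], patients: Iterable[Patient] | None = None
) -> dict[str, pd.Series]:
    """Empirical marginal distributions of the generated cohort.

    Returns normalised distributions of whole-spell transfer counts and
    dominant TFC, length-of-stay quantiles, and (when ``patients`` is
    supplied) age-band shares.  Each probability vector sums to 1.
    """
    if len(spells) == 0:
        raise ValueError("cannot summarise an empty spell list")
    transfers = pd.Series([count_spell_transfers(sp) for sp in spells])
    tfc = pd.Series(
        [max(sp.episodes, key=lambda e: e.duration).tfc if sp.episodes else None for sp in spells]
    )
    los = pd.Series([sp.duration for sp in spells])
    out = {
        "transfers": transfers.value_counts(normalize=True).sort_index(),
        "tfc": tfc.value_counts(normalize=True),
        "los_quantiles": los.quantile([0.25, 0.5, 0.75]),
    }
    if patients is not None:
        ages = pd.Series([p.age_at_admission for p in patients])
        bands = pd.cut(
            ages,
            bins=[0, 65, 71, 76, 81, 86, np.inf],
            right=False,
            labels=["<65", "65-70", "71-75", "76-80", "81-85", "86+"],
        )
        out["age_bands"] = bands.value_counts(normalize=True).sort_index()
    return out


# ----------------------------------------------------------------------
# CSV round-trip

TABLE_NAMES = ("patients", "spells", "ward_stays", "episodes", "micro")


def to_frames(patients: Sequence[Patient], spells: Sequence[Spell]) -> dict[str, pd.DataFrame]:
    """Flatten the object graph into the five relational tables."""
    pat = pd.DataFrame(
        [(p.patient_id, p.age_at_admission, p.gender, p.ethnicity) for p in patients],
        columns=["patient_id", "age_at_admission", "gender", "ethnicity"],
    )
    sp_rows, ws_rows, ep_rows, mi_rows = [], [], [], []
    for sp in spells:
        sp_rows.append(
            (
                sp.spell_id,
                sp.patient_id,
                sp.hospital_site,
                sp.admission_time,
                sp.discharge_time,
                sp.admission_class,
                sp.discharge_destination,
                sp.died_in_hospital,
            )
        )
        for w in sp.ward_stays:
            ws_rows.append((sp.spell_id, w.ward_id, w.entry_time, w.exit_time, w.is_icu))
        for e in sp.episodes:
            ep_rows.append(
                (
                    sp.spell_id,
                    e.episode_start,
                    e.episode_end,
                    e.tfc,
                    ";".join(e.icd10_codes),
                    e.opcs4_count,
                    ";".join(e.opcs4_codes),
                )
            )
        for m in sp.samples:
            mi_rows.append(
                (sp.spell_id, m.collection_time, m.organism or "", m.specimen_site or "", m.positive)
            )
    return {
        "patients": pat,
        "spells": pd.DataFrame(
            sp_rows,
            columns=[
                "spell_id",
                "patient_id",
                "hospital_site",
                "admission_time",
                "discharge_time",
                "admission_class",
                "discharge_destination",
                "died_in_hospital",
            ],
        ),
        "ward_stays": pd.DataFrame(
            ws_rows, columns=["spell_id", "ward_id", "entry_time", "exit_time", "is_icu"]
        ),
        "episodes": pd.DataFrame(
            ep_rows,
            columns=[
                "spell_id",
                "episode_start",
                "episode_end",
                "tfc",
                "icd10_codes",
                "opcs4_count",
                "opcs4_codes",
            ],
        ),
        "micro": pd.DataFrame(
            mi_rows, columns=["spell_id", "collection_time", "organism", "specimen_site", "positive"]
        ),
    }


def write_tables(patients: Sequence[Patient], spells: Sequence[Spell], directory) -> dict[str, str]:
    """Write the five CSV tables; returns table name -> file path."""
    os.makedirs(directory, exist_ok=True)
    frames = to_frames(patients, spells)
    paths = {}
    for name, frame in frames.items():
        path = os.path.join(directory, f"{name}.csv")
        # %.17g keeps fractional-day timestamps exact through the round trip
        frame.to_csv(path, index=False, float_format="%.17g")
        paths[name] = path
    return paths


def _split_codes(raw) -> list[str]:
    if isinstance(raw, str) and raw:
        return raw.split(";")
    return []


def read_tables(directory) -> tuple[list[Patient], list[Spell]]:
    """Load the five-table CSV schema back into the object graph."""
    frames = {}
    for name in TABLE_NAMES:
        path = os.path.join(directory, f"{name}.csv")
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        frames[name] = pd.read_csv(path, float_precision="round_trip")

    patients = [
        Patient(r.patient_id, int(r.age_at_admission), r.gender, r.ethnicity)
        for r in frames["patients"].itertuples()
    ]
    spell_map: dict[str, Spell] = {}
    spells: list[Spell] = []
    for r in frames["spells"].itertuples():
        sp = Spell(
            r.spell_id,
            r.patient_id,
            int(r.hospital_site),
            float(r.admission_time),
            float(r.discharge_time),
            r.admission_class,
            r.discharge_destination,
            bool(r.died_in_hospital),
        )
        spell_map[sp.spell_id] = sp
        spells.append(sp)
    for r in frames["ward_stays"].itertuples():
        spell_map[r.spell_id].ward_stays.append(
            WardStay(r.ward_id, float(r.entry_time), float(r.exit_time), bool(r.is_icu))
        )
    for r in frames["episodes"].itertuples():
        spell_map[r.spell_id].episodes.append(
            ConsultantEpisode(
                float(r.episode_start),
                float(r.episode_end),
                r.tfc,
                _split_codes(r.icd10_codes),
                int(r.opcs4_count),
                _split_codes(getattr(r, "opcs4_codes", "")),
            )
        )
    for r in frames["micro"].itertuples():
        organism = r.organism if isinstance(r.organism, str) and r.organism else None
        site = r.specimen_site if isinstance(r.specimen_site, str) and r.specimen_site else None
        spell_map[r.spell_id].samples.append(
            MicroSample(float(r.collection_time), organism, site, bool(r.positive))
        )
    for sp in spells:
        sp.ward_stays.sort(key=lambda w: w.entry_time)
        sp.episodes.sort(key=lambda e: e.episode_start)
        sp.samples.sort(key=lambda m: m.collection_time)
    return patients, spells
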