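"""Elixhauser comorbidity indicators from ICD-10 codes.

The Elixhauser system defines 31 comorbidity indicator groups.  Each
group is keyed here to a set of ICD-10 code prefixes (the widely used
enhanced ICD-10 coding); a diagnosis code belongs to a group when it
starts with one of the group's prefixes after normalisation (uppercase,
dot removed).  The comorbidity burden of a spell is the number of
DISTINCT groups observed among the codes of the qualifying episodes —
duplicate codes, and several codes falling in one group, count once.

Codes are matched by the LONGEST matching prefix across all groups, so
the handful of specific codes that belong to a more specific group than
their three-character parent (e.g. I11* under complicated hypertension
rather than uncomplicated) resolve deterministically.
"""

from __future__ import annotations

import warnings

#: group name -> tuple of ICD-10 prefixes (normalised: no dot, uppercase).
ELIXHAUSER_ICD10: dict[str, tuple[str, ...]] = {
    "congestive_heart_failure": ("I50", "I099", "I110", "I130", "I132", "I255", "I420", "I425", "I428", "I429", "P290"),
    "cardiac_arrhythmia": ("I44", "I45", "I47", "I48", "I49", "R000", "R001", "R008", "T821", "Z450", "Z950"),
    "valvular_disease": ("I05", "I06", "I07", "I08", "I091", "I098", "I34", "I35", "I36", "I37", "I38", "I39", "Q230", "Q231", "Q232", "Q233", "Z952", "Z953", "Z954"),
    "pulmonary_circulation": ("I26", "I27", "I280", "I288", "I289"),
    "peripheral_vascular": ("I70", "I71", "I731", "I738", "I739", "I771", "I790", "I792", "K551", "K558", "K559", "Z958", "Z959"),
    "hypertension_uncomplicated": ("I10",),
    "hypertension_complicated": ("I11", "I12", "I13", "I15"),
    "paralysis": ("G041", "G114", "G801", "G802", "G81", "G82", "G830", "G831", "G832", "G833", "G834", "G839"),
    "other_neurological": ("G10", "G11", "G12", "G13", "G20", "G21", "G22", "G254", "G255", "G312", "G318", "G319", "G32", "G35", "G36", "G37", "G40", "G41", "G931", "G934", "R470", "R56"),
    "chronic_pulmonary": ("I278", "I279", "J40", "J41", "J42", "J43", "J44", "J45", "J46", "J47", "J60", "J61", "J62", "J63", "J64", "J65", "J66", "J67", "J684", "J701", "J703"),
    "diabetes_uncomplicated": ("E100", "E101", "E109", "E110", "E111", "E119", "E120", "E121", "E129", "E130", "E131", "E139", "E140", "E141", "E149"),
    "diabetes_complicated": ("E102", "E103", "E104", "E105", "E106", "E107", "E108", "E112", "E113", "E114", "E115", "E116", "E117", "E118", "E122", "E123", "E124", "E125", "E126", "E127", "E128", "E132", "E133", "E134", "E135", "E136", "E137", "E138", "E142", "E143", "E144", "E145", "E146", "E147", "E148"),
    "hypothyroidism": ("E00", "E01", "E02", "E03", "E890"),
    "renal_failure": ("N18", "N19", "N250", "I120", "I131", "Z490", "Z491", "Z492", "Z940", "Z992"),
    "liver_disease": ("B18", "I85", "I864", "I982", "K70", "K711", "K713", "K714", "K715", "K717", "K72", "K73", "K74", "K760", "K762", "K763", "K764", "K765", "K766", "K767", "K768", "K769", "Z944"),
    "peptic_ulcer": ("K257", "K259", "K267", "K269", "K277", "K279", "K287", "K289"),
    "aids_hiv": ("B20", "B21", "B22", "B24"),
    "lymphoma": ("C81", "C82", "C83", "C84", "C85", "C88", "C96", "C900", "C902"),
    "metastatic_cancer": ("C77", "C78", "C79", "C80"),
    "solid_tumour": ("C00", "C01", "C02", "C03", "C04", "C05", "C06", "C07", "C08", "C09", "C10", "C11", "C12", "C13", "C14", "C15", "C16", "C17", "C18", "C19", "C20", "C21", "C22", "C23", "C24", "C25", "C26", "C30", "C31", "C32", "C33", "C34", "C37", "C38", "C39", "C40", "C41", "C43", "C45", "C46", "C47", "C48", "C49", "C50", "C51", "C52", "C53", "C54", "C55", "C56", "C57", "C58", "C60", "C61", "C62", "C63", "C64", "C65", "C66", "C67", "C68", "C69", "C70", "C71", "C72", "C73", "C74", "C75", "C76", "C97"),
    "rheumatoid_collagen": ("L940", "L941", "L943", "M05", "M06", "M08", "M120", "M123", "M30", "M310", "M311", "M312", "M313", "M32", "M33", "M34", "M35", "M45", "M461", "M468", "M469"),
    "coagulopathy": ("D65", "D66", "D67", "D68", "D691", "D693", "D694", "D695", "D696"),
    "obesity": ("E66",),
    "weight_loss": ("E40", "E41", "E42", "E43", "E44", "E45", "E46", "R634", "R64"),
    "fluid_electrolyte": ("E222", "E86", "E87"),
    "blood_loss_anemia": ("D500",),
    "deficiency_anemia": ("D508", "D509", "D51", "D52", "D53"),
    "alcohol_abuse": ("F10", "E52", "G621", "K292", "K700", "K703", "K709", "T51", "Z502", "Z714", "Z721"),
    "drug_abuse": ("F11", "F12", "F13", "F14", "F15", "F16", "F18", "F19", "Z715", "Z722"),
    "psychoses": ("F20", "F22", "F23", "F24", "F25", "F28", "F29", "F302", "F315"),
    "depression": ("F204", "F313", "F314", "F32", "F33", "F341", "F412", "F432"),
}

INDICATOR_NAMES: tuple[str, ...] = tuple(ELIXHAUSER_ICD10)
N_INDICATORS = len(INDICATOR_NAMES)
assert N_INDICATORS == 31

#: one canonical code per group; the synthetic generator emits exactly
#: these, which makes comorbidity counting invertible in tests.
REPRESENTATIVE_CODES: dict[str, str] = {
    # 3-char prefixes are padded with "9", which never collides with a
    # 4-char prefix claimed by another group (e.g. I11 -> I119, not the
    # heart-failure code I110), so classify_code inverts this map.
    group: prefixes[0] if len(prefixes[0]) == 4 else prefixes[0] + "9"
    for group, prefixes in ELIXHAUSER_ICD10.items()
}

# longest-prefix lookup table, built once
_PREFIX_TO_GROUP: dict[str, str] = {}
for _group, _prefixes in ELIXHAUSER_ICD10.items():
    for _p in _prefixes:
        _PREFIX_TO_GROUP.setdefault(_p, _group)


def normalize_code(code: str) -> str:
    return code.replace(".", "").replace(" ", "").upper()


def classify_code(code: str) -> str | None:
    """Map one ICD-10 code to its Elixhauser group, or None.

    Malformed codes (empty, or not letter-led) trigger a warning and
    return None rather than raising: diagnosis lists in routine data are
    noisy and a single bad code should not abort a spell.
    """
    norm = normalize_code(code)
    if not norm or not norm[0].isalpha() or len(norm) < 3:
        warnings.warn(f"skipping malformed ICD-10 code {code!r}", stacklevel=2)
        return None
    # longest prefix wins (prefixes are 3 or 4 chars after normalisation)
    for length in (4, 3):
        group = _PREFIX_TO_GROUP.get(norm[:length])
        if group is not None:
            return group
    return None


def count_indicators(codes) -> int:
    """Number of distinct Elixhauser groups represented in ``codes``."""
    groups = {classify_code(c) for c in codes}
    groups.discard(None)
    return len(groups)
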