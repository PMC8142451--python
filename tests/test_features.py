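"""Index-censored covariate derivation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nosoflow import (
    ConsultantEpisode,
    OutcomeAssignment,
    WardStay,
    count_transfers,
    dominant_tfc,
    elixhauser_count,
    icu_flag,
    interpolate_procedures,
    time_at_risk,
)
from nosoflow.features import (
    age_band,
    bin_covariates,
    build_analysis_records,
    elixhauser_band,
    procedures_band,
    time_at_risk_band,
)

from conftest import make_patient, make_spell


def stays(*specs):
    return [WardStay(w, a, b, len(s) > 3 and s[3]) for s in specs for w, a, b in [s[:3]]]


class TestTimeAtRisk:
    def test_control_runs_to_discharge(self):
        sp = make_spell(discharge=10.0)
        assert time_at_risk(sp, OutcomeAssignment("S1", "control", 10.0)) == 10.0

    def test_case_runs_to_first_positive(self):
        sp = make_spell(discharge=10.0)
        assert time_at_risk(sp, OutcomeAssignment("S1", "case", 6.3)) == 6.3

    def test_boundary_two_days(self):
        sp = make_spell(discharge=10.0)
        assert time_at_risk(sp, OutcomeAssignment("S1", "case", 2.0)) == 2.0

    def test_index_before_admission_rejected(self):
        sp = make_spell(admission=5.0, discharge=10.0)
        with pytest.raises(ValueError):
            time_at_risk(sp, OutcomeAssignment("S1", "case", 4.0))


class TestCountTransfers:
    def test_single_ward_is_zero(self):
        assert count_transfers(stays(("A", 0, 10)), 10.0) == 0

    def test_return_to_previous_ward_counts(self):
        ws = stays(("A", 0, 2), ("B", 2, 5), ("A", 5, 10))
        assert count_transfers(ws, 10.0) == 2

    def test_boundary_after_index_not_counted(self):
        ws = stays(("A", 0, 2), ("B", 2, 5), ("C", 5, 9))
        assert count_transfers(ws, 4.0) == 1

    def test_boundary_exactly_at_index_not_counted(self):
        ws = stays(("A", 0, 2), ("B", 2, 5))
        assert count_transfers(ws, 2.0) == 0

    def test_same_ward_bed_move_not_counted(self):
        ws = stays(("A", 0, 4), ("A", 4, 10))
        assert count_transfers(ws, 10.0) == 0

    def test_unordered_stays_rejected(self):
        ws = stays(("B", 2, 5), ("A", 0, 2))
        with pytest.raises(ValueError):
            count_transfers(ws, 10.0)

    @given(
        n=st.integers(1, 8),
        index=st.floats(0.0, 12.0),
        data=st.data(),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_brute_force_pairwise_scan(self, n, index, data):
        bounds = sorted(
            data.draw(st.lists(st.floats(0.01, 11.99), min_size=n - 1, max_size=n - 1, unique=True))
        )
        edges = [0.0] + bounds + [12.0]
        wards = [data.draw(st.sampled_from("ABC")) for _ in range(n)]
        ws = stays(*[(w, a, b) for w, a, b in zip(wards, edges, edges[1:])])
        brute = sum(
            1
            for i in range(1, n)
            if ws[i].ward_id != ws[i - 1].ward_id and ws[i].entry_time < index
        )
        assert count_transfers(ws, index) == brute

    def test_equals_stay_count_minus_one_when_all_wards_differ(self):
        ws = stays(("A", 0, 1), ("B", 1, 2), ("C", 2, 3), ("A", 3, 4))
        began_before = sum(1 for w in ws if w.entry_time < 3.5)
        assert count_transfers(ws, 3.5) == began_before - 1


class TestInterpolateProcedures:
    def test_single_straddling_episode(self):
        eps = [ConsultantEpisode(10.0, 14.0, "cardiology", [], 8)]
        assert interpolate_procedures(eps, 11.0) == pytest.approx(2.0)

    def test_completed_plus_straddling(self):
        eps = [
            ConsultantEpisode(0.0, 3.0, "cardiology", [], 4),
            ConsultantEpisode(3.0, 9.0, "cardiology", [], 6),
        ]
        assert interpolate_procedures(eps, 6.0) == pytest.approx(7.0)

    def test_index_at_episode_end_counts_fully(self):
        eps = [ConsultantEpisode(0.0, 4.0, "cardiology", [], 5)]
        assert interpolate_procedures(eps, 4.0) == 5.0

    def test_control_limit_is_plain_sum(self):
        eps = [
            ConsultantEpisode(0.0, 3.0, "cardiology", [], 4),
            ConsultantEpisode(3.0, 9.0, "geriatric_medicine", [], 6),
        ]
        assert interpolate_procedures(eps, 9.0) == 10.0

    def test_zero_length_episode_rejected(self):
        with pytest.raises(ValueError):
            interpolate_procedures([ConsultantEpisode(2.0, 2.0, "cardiology", [], 1)], 2.0)


class TestElixhauserCount:
    def test_distinct_indicators(self):
        # two heart-failure codes and one diabetes code -> 2 indicators
        eps = [ConsultantEpisode(0.0, 5.0, "cardiology", ["I509", "I099", "E119"], 0)]
        assert elixhauser_count(eps, 5.0) == 2

    def test_episodes_started_at_or_after_index_ignored(self):
        eps = [
            ConsultantEpisode(0.0, 3.0, "cardiology", [], 0),
            ConsultantEpisode(3.0, 9.0, "cardiology", ["I509"], 0),
        ]
        assert elixhauser_count(eps, 3.0) == 0
        assert elixhauser_count(eps, 3.5) == 1


class TestDominantTfc:
    def test_longest_duration_wins(self):
        eps = [
            ConsultantEpisode(0.0, 3.0, "cardiology"),
            ConsultantEpisode(3.0, 8.0, "geriatric_medicine"),
        ]
        assert dominant_tfc(eps, 8.0) == "geriatric_medicine"

    def test_exact_tie_broken_by_earliest_occurrence(self):
        eps = [
            ConsultantEpisode(0.0, 4.0, "cardiology"),
            ConsultantEpisode(4.0, 8.0, "nephrology"),
        ]
        assert dominant_tfc(eps, 8.0) == "cardiology"

    def test_straddling_episode_truncated_at_index(self):
        eps = [
            ConsultantEpisode(0.0, 3.0, "cardiology"),
            ConsultantEpisode(3.0, 10.0, "geriatric_medicine"),
        ]
        # untruncated, geriatrics dominates (7 d); before index 5.0 it holds 2 d
        assert dominant_tfc(eps, 10.0) == "geriatric_medicine"
        assert dominant_tfc(eps, 5.0) == "cardiology"

    def test_no_episode_before_index_errors(self):
        with pytest.raises(ValueError):
            dominant_tfc([ConsultantEpisode(5.0, 9.0, "cardiology")], 5.0)


class TestIcuFlag:
    @pytest.mark.parametrize(
        "entry,index,expected", [(3.0, 5.0, True), (6.0, 5.0, False), (5.0, 5.0, False)]
    )
    def test_entry_strictly_before_index(self, entry, index, expected):
        ws = stays(("A", 0, entry), ("ICU-1", entry, 10.0, True))
        assert icu_flag(ws, index) is expected

    def test_no_icu_stay(self):
        assert icu_flag(stays(("A", 0, 10)), 10.0) is False


class TestBanding:
    @pytest.mark.parametrize(
        "age,band", [(65, "65-70"), (70, "65-70"), (71, "71-75"), (85, "81-85"), (86, "86+"), (99, "86+")]
    )
    def test_age_bands_inclusive(self, age, band):
        assert age_band(age) == band

    @pytest.mark.parametrize("t,band", [(2.0, "2-5"), (5.0, "5-7"), (39.99, "30-40"), (40.0, "40+")])
    def test_time_bands_left_closed(self, t, band):
        assert time_at_risk_band(t) == band

    @pytest.mark.parametrize("k,band", [(0, "0"), (1, "1-3"), (3, "1-3"), (4, "4-6"), (10, "10+")])
    def test_elixhauser_bands(self, k, band):
        assert elixhauser_band(k) == band

    def test_fractional_procedures_floored(self):
        assert procedures_band(8.9) == "2-8"
        assert procedures_band(0.7) == "0"

    def test_below_lowest_band_errors(self):
        with pytest.raises(ValueError):
            age_band(64)
        with pytest.raises(ValueError):
            time_at_risk_band(1.5)


def test_censoring_monotonicity():
    """Transfers, procedures and comorbidity count never decrease as the
    index moves later through the spell."""
    sp = make_spell(
        discharge=12.0,
        wards=[("A", 0, 3), ("B", 3, 6), ("ICU-1", 6, 8, True), ("A", 8, 12)],
        episodes=[(0.0, 4.0, "cardiology", ["I509"], 3), (4.0, 12.0, "geriatric_medicine", ["E119"], 6)],
    )
    grid = np.linspace(2.0, 12.0, 41)
    transfers = [count_transfers(sp.ward_stays, t) for t in grid]
    procs = [interpolate_procedures(sp.episodes, t) for t in grid]
    elix = [elixhauser_count(sp.episodes, t) for t in grid]
    for series in (transfers, procs, elix):
        assert all(b >= a for a, b in zip(series, series[1:]))


def test_build_analysis_records_row_content():
    sp = make_spell(
        discharge=12.0,
        wards=[("A", 0, 3), ("B", 3, 12)],
        episodes=[(0.0, 12.0, "cardiology", ["I509", "E119"], 6)],
        samples=[(6.0, "Escherichia coli", "blood", True)],
    )
    assignment = OutcomeAssignment("S1", "case", 6.0, "Escherichia coli", "blood")
    records = build_analysis_records([sp], [assignment], [make_patient(age=72)])
    row = records.iloc[0]
    assert row["case"] == 1
    assert row["time_at_risk"] == 6.0
    assert row["n_transfers"] == 1
    assert row["procedures"] == pytest.approx(3.0)  # 6 * 6/12
    assert row["elixhauser_count"] == 2
    assert row["age_band"] == "71-75" and row["time_band"] == "5-7"
    assert row["proc_band"] == "2-8" and row["elix_band"] == "1-3"


def test_band_edges_configurable_via_yaml(tmp_path):
    from nosoflow.features import load_band_config

    path = tmp_path / "bands.yaml"
    path.write_text(
        "time_at_risk:\n  edges: [2, 10, .inf]\n  labels: ['2-10', '10+']\n"
    )
    config = load_band_config(path)
    records = pd.DataFrame(
        {"age": [70], "time_at_risk": [12.0], "elixhauser_count": [2], "procedures": [3.0]}
    )
    banded = bin_covariates(records, band_config=config)
    assert banded.loc[0, "time_band"] == "10+"
    assert banded.loc[0, "age_band"] == "65-70"  # other fields keep defaults


def test_bin_covariates_consistent_with_underlying_values(medium_cohort):
    from nosoflow import apply_exclusions, classify_spell

    _, patients, spells = medium_cohort
    included, _ = apply_exclusions(spells, patients)
    assignments = [classify_spell(sp) for sp in included[:500]]
    records = build_analysis_records(included[:500], assignments, patients)
    rebanded = bin_covariates(records)
    for col in ("age_band", "time_band", "elix_band", "proc_band"):
        assert (rebanded[col] == records[col]).all()
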