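"""Logistic fits against closed-form oracles; tables; clustering."""

import numpy as np
import pandas as pd
import pytest

from nosoflow import (
    chi_square_table,
    descriptive_table,
    fit_logistic,
    icc_from_variance,
    icc_site,
    screen_covariates,
)
from nosoflow.inference import SeparationError


def two_by_two(a, b, c, d):
    """Records for an exposed/unexposed case/control table."""
    rows = (
        [{"case": 1, "exposed": 1}] * a
        + [{"case": 0, "exposed": 1}] * b
        + [{"case": 1, "exposed": 0}] * c
        + [{"case": 0, "exposed": 0}] * d
    )
    return pd.DataFrame(rows)


class TestFitLogistic:
    def test_saturated_2x2_matches_cross_product_oracle(self):
        a, b, c, d = 10, 90, 5, 95
        result = fit_logistic(two_by_two(a, b, c, d), terms=["exposed"])
        oracle = (a * d) / (b * c)
        assert result.term("exposed").odds_ratio == pytest.approx(oracle, abs=1e-6)

    @pytest.mark.parametrize("a,b,c,d", [(20, 80, 20, 80), (33, 11, 7, 29), (5, 200, 50, 100)])
    def test_cross_product_equivalence_various_tables(self, a, b, c, d):
        result = fit_logistic(two_by_two(a, b, c, d), terms=["exposed"])
        assert result.term("exposed").odds_ratio == pytest.approx(a * d / (b * c), rel=1e-6)

    def test_independent_balanced_term_gives_null_or(self):
        rng = np.random.default_rng(4)
        n = 20000
        records = pd.DataFrame(
            {"case": rng.integers(0, 2, n), "exposed": rng.integers(0, 2, n)}
        )
        row = fit_logistic(records, terms=["exposed"]).term("exposed")
        assert row.ci_low < 1.0 < row.ci_high

    def test_wald_ci_brackets_the_or(self):
        result = fit_logistic(two_by_two(10, 90, 5, 95), terms=["exposed"])
        row = result.term("exposed")
        assert row.ci_low <= row.odds_ratio <= row.ci_high and row.odds_ratio > 0

    def test_categorical_reference_is_first_level(self):
        records = two_by_two(10, 90, 5, 95)
        records["grp"] = pd.Categorical(
            np.where(records["exposed"] == 1, "moved", "stayed"),
            categories=["stayed", "moved"],
        )
        result = fit_logistic(records, terms=["grp"])
        assert result.term("grp[moved]").odds_ratio == pytest.approx(10 * 95 / (90 * 5), rel=1e-6)

    def test_single_outcome_class_rejected(self):
        records = pd.DataFrame({"case": [1, 1, 1], "exposed": [0, 1, 0]})
        with pytest.raises(ValueError, match="both classes"):
            fit_logistic(records, terms=["exposed"])

    def test_single_level_term_rejected(self):
        records = pd.DataFrame({"case": [1, 0, 1], "exposed": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="constant"):
            fit_logistic(records, terms=["exposed"])

    def test_perfect_separation_names_the_term(self):
        records = two_by_two(50, 0, 0, 50)
        with pytest.raises(SeparationError, match="exposed"):
            fit_logistic(records, terms=["exposed"])

    def test_parameter_recovery_on_synthetic_cohort(self, medium_cohort):
        from nosoflow import run_analysis

        config, patients, spells = medium_cohort
        result = run_analysis(patients, spells)
        row = result.multivariable.term("n_transfers")
        assert row.ci_low <= np.exp(config.beta_transfer) <= row.ci_high


class TestScreenCovariates:
    def test_noise_covariate_dropped_at_nominal_rate(self):
        rng = np.random.default_rng(12)
        n = 2000
        dropped = 0
        for _ in range(100):
            records = pd.DataFrame(
                {"case": rng.integers(0, 2, n), "noise": rng.normal(size=n)}
            )
            if "noise" not in screen_covariates(records, ["noise"]):
                dropped += 1
        assert dropped >= 94

    def test_gender_kept_a_priori_even_when_null(self):
        rng = np.random.default_rng(5)
        records = pd.DataFrame(
            {
                "case": rng.integers(0, 2, 500),
                "gender": rng.choice(["female", "male"], 500),
            }
        )
        assert "gender" in screen_covariates(records, ["gender"])

    def test_strong_covariate_retained(self, medium_cohort):
        from nosoflow import build_cohort

        _, patients, spells = medium_cohort
        records = build_cohort(patients, spells).records
        retained = screen_covariates(
            records, ["n_transfers", "elix_band", "icu_before_index", "ethnicity"]
        )
        assert "n_transfers" in retained and "elix_band" in retained

    def test_missing_candidate_errors(self):
        with pytest.raises(KeyError):
            screen_covariates(pd.DataFrame({"case": [0, 1]}), ["ghost"])


class TestChiSquare:
    def test_balanced_table_gives_zero(self):
        records = pd.DataFrame(
            {"status": ["case"] * 100 + ["control"] * 100, "band": (["a"] * 50 + ["b"] * 50) * 2}
        )
        stat, df, p = chi_square_table(records, "band")
        assert stat == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_matches_hand_computed_pearson_sum(self):
        # table [[20, 10], [10, 20]]
        records = pd.DataFrame(
            {
                "status": ["case"] * 30 + ["control"] * 30,
                "band": ["a"] * 20 + ["b"] * 10 + ["a"] * 10 + ["b"] * 20,
            }
        )
        observed = np.array([[20, 10], [10, 20]])
        expected = np.outer(observed.sum(1), observed.sum(0)) / observed.sum()
        hand = ((observed - expected) ** 2 / expected).sum()
        stat, df, _ = chi_square_table(records, "band")
        assert stat == pytest.approx(hand) and df == 1

    def test_single_band_covariate_errors(self):
        records = pd.DataFrame({"status": ["case", "control"], "band": ["a", "a"]})
        with pytest.raises(ValueError):
            chi_square_table(records, "band")


@pytest.fixture(scope="module")
def icu_records():
    """Reconstruction of the printed ICU row: 193 of 2877 cases and
    405 of 21363 controls attended ICU."""
    rows = []
    for status, icu_yes, total in (("case", 193, 2877), ("control", 405, 21363)):
        rows += [{"status": status, "icu_before_index": True}] * icu_yes
        rows += [{"status": status, "icu_before_index": False}] * (total - icu_yes)
    return pd.DataFrame(rows)


class TestDescriptiveTable:
    def test_icu_share_among_cases(self, icu_records):
        table = descriptive_table(
            icu_records, covariates=("icu_before_index",), continuous=()
        ).bands
        row = table[table["level"] == True].iloc[0]  # noqa: E712
        assert row["cases_pct"] == pytest.approx(6.71, abs=0.005)
        assert row["controls_pct"] == pytest.approx(1.90, abs=0.005)

    def test_all_control_input_zeroes_case_column(self):
        records = pd.DataFrame({"status": ["control"] * 10, "band": ["a", "b"] * 5})
        table = descriptive_table(records, covariates=("band",), continuous=()).bands
        assert (table["cases_n"] == 0).all() and (table["cases_pct"] == 0).all()

    def test_column_percentages_sum_to_100(self, medium_cohort):
        from nosoflow import build_cohort

        _, patients, spells = medium_cohort
        records = build_cohort(patients, spells).records
        table = descriptive_table(records).bands
        for cov, part in table.groupby("covariate"):
            for col in ("all_pct", "controls_pct", "cases_pct"):
                assert part[col].sum() == pytest.approx(100.0, abs=0.01)

    def test_markdown_rendering(self, icu_records):
        table = descriptive_table(icu_records, covariates=("icu_before_index",), continuous=())
        md = table.to_markdown()
        assert md.startswith("| covariate |") and "| --- |" in md

    def test_counts_invariant_to_record_order(self, medium_cohort):
        from nosoflow import build_cohort

        _, patients, spells = medium_cohort
        records = build_cohort(patients, spells).records
        shuffled = records.sample(frac=1.0, random_state=1)
        t1 = descriptive_table(records).bands
        t2 = descriptive_table(shuffled).bands
        pd.testing.assert_frame_equal(t1.reset_index(drop=True), t2.reset_index(drop=True))


class TestIcc:
    def test_closed_form_endpoints(self):
        assert icc_from_variance(0.0) == 0.0
        assert icc_from_variance(np.pi**2 / 3) == pytest.approx(0.5)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            icc_from_variance(-0.1)

    def test_single_cluster_errors(self):
        records = pd.DataFrame({"case": [0, 1, 0], "hospital_site": [1, 1, 1]})
        with pytest.raises(ValueError, match="clusters"):
            icc_site(records)

    def test_null_site_effects_give_near_zero_icc(self):
        rng = np.random.default_rng(8)
        n = 12000
        records = pd.DataFrame(
            {
                "case": (rng.random(n) < 0.12).astype(int),
                "hospital_site": rng.choice([1, 2, 3], n),
            }
        )
        result = icc_site(records)
        assert 0.0 <= result.icc < 0.01

    def test_matches_independent_glmm_oracle(self):
        """Frozen oracle: an adaptive-quadrature GLMM fit (lme4, nAGQ=25)
        of this exact simulated dataset gives between-cluster variance
        0.123029."""
        rng = np.random.default_rng(15)
        n = 8000
        site = rng.choice([1, 2, 3, 4, 5, 6], n)
        effect = {1: -0.6, 2: -0.2, 3: 0.0, 4: 0.1, 5: 0.3, 6: 0.6}
        eta = -2.0 + np.vectorize(effect.get)(site)
        records = pd.DataFrame(
            {"case": (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int), "hospital_site": site}
        )
        result = icc_site(records)
        assert result.between_variance == pytest.approx(0.123029, abs=1e-3)

    def test_recovers_injected_site_heterogeneity(self):
        rng = np.random.default_rng(15)
        n = 12000
        site = rng.choice([1, 2, 3], n)
        effect = {1: -0.8, 2: 0.0, 3: 0.8}
        eta = -2.0 + np.vectorize(effect.get)(site)
        records = pd.DataFrame(
            {"case": (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int), "hospital_site": site}
        )
        result = icc_site(records)
        assert result.between_variance > 0.1
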