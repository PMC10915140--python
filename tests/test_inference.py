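import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from oracles import yates_chi2_textbook
from smrhythm.exceptions import (
    DegenerateDesignError,
    InsufficientDataError,
    InvalidParameterError,
    InvalidTableError,
    UndefinedPercentError,
)
from smrhythm.inference import (
    DEFAULT_ORDER,
    ModelComparisonResult,
    PredictorStat,
    bic_bayes_factor,
    clinical_regression,
    percent_effect,
    prepare_design,
    sequential_bf,
    welch_t_test,
    yates_chi_square,
)
from smrhythm.synthgen import CohortParams, generate_cohort


def small_cohort(seed=0, **kwargs):
    return generate_cohort(CohortParams(n_pd=40, n_hc=40, seed=seed, **kwargs))


class TestPrepareDesign:
    def test_zero_variance_age_raises(self):
        table = small_cohort()
        table["age"] = 60.0
        with pytest.raises(DegenerateDesignError):
            prepare_design(table, "beta_power")

    def test_log_transform_before_zscore(self):
        table = small_cohort()
        # plant a geometric progression; its logs are an arithmetic one
        values = np.exp(1.0 + np.arange(len(table)) % 3)
        table["burst_duration"] = values
        design = prepare_design(table, "burst_duration")
        logs = np.log(values)
        expected = (logs - logs.mean()) / logs.std(ddof=0)
        np.testing.assert_allclose(design.y, expected, atol=1e-12)

    def test_design_matrix_matches_hand_built_oracle(self):
        table = small_cohort(seed=3)
        design = prepare_design(table, "beta_power")
        age = table["age"].to_numpy()
        thick = table["cortical_thickness"].to_numpy()
        group = (table["group"] == "pd").astype(float).to_numpy()
        sex = (table["sex"] == "male").astype(float).to_numpy()
        age_z = (age - age.mean()) / age.std()
        thick_z = (thick - thick.mean()) / thick.std()
        oracle = {
            "group": group,
            "age": age_z,
            "age2": age_z**2,
            "sex": sex,
            "thickness": thick_z,
            "age:group": age_z * group,
            "age:sex": age_z * sex,
            "age:thickness": age_z * thick_z,
            "group:sex": group * sex,
            "group:thickness": group * thick_z,
            "sex:thickness": sex * thick_z,
        }
        assert set(design.X.columns) == set(oracle)
        for name, column in oracle.items():
            np.testing.assert_allclose(design.X[name].to_numpy(), column, atol=1e-12)

    def test_burst_rate_uses_counts_and_exposure(self):
        table = small_cohort()
        design = prepare_design(table, "burst_rate")
        assert design.family == "poisson"
        np.testing.assert_allclose(design.y, table["n_events"].to_numpy())
        np.testing.assert_allclose(design.exposure, table["analyzed_s"].to_numpy() / 60.0)

    def test_missing_outcome_rows_dropped(self):
        table = small_cohort()
        table.loc[table.index[:5], "alpha_power"] = np.nan
        design = prepare_design(table, "alpha_power")
        assert design.n == len(table) - 5

    def test_too_few_rows_raises(self):
        table = small_cohort().head(5)
        with pytest.raises(InsufficientDataError):
            prepare_design(table, "beta_power")


class TestBicBayesFactor:
    def test_equal_bics_give_unit_bf(self):
        assert bic_bayes_factor(12.3, 12.3) == pytest.approx(1.0)

    def test_two_log_three_gives_bf_three(self):
        assert bic_bayes_factor(2 * np.log(3.0), 0.0) == pytest.approx(3.0)

    def test_toy_regression_matches_hand_bic(self):
        rng = np.random.default_rng(1)
        n = 20
        table = pd.DataFrame(
            {
                "group": ["pd"] * 10 + ["hc"] * 10,
                "age": rng.uniform(50, 80, n),
                "sex": ["female", "male"] * 10,
                "cortical_thickness": rng.normal(2.5, 0.2, n),
                "beta_power": rng.normal(0.0, 1.0, n),
            }
        )
        result = sequential_bf(table, "beta_power", order=("group",))
        # Hand-computed BIC difference: n ln(RSS/n) + p ln(n), constants cancel.
        y = table["beta_power"].to_numpy()
        y = (y - y.mean()) / y.std()
        g = (table["group"] == "pd").astype(float).to_numpy()
        rss0 = np.sum((y - y.mean()) ** 2)
        X = np.column_stack([np.ones(n), g])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss1 = np.sum((y - X @ beta) ** 2)
        delta = (n * np.log(rss0 / n) + 2 * np.log(n)) - (
            n * np.log(rss1 / n) + 3 * np.log(n)
        )
        assert result.stats["group"].bf10 == pytest.approx(np.exp(delta / 2), rel=1e-9)

    @given(
        a=st.floats(-50, 50, allow_nan=False),
        b=st.floats(-50, 50, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_reciprocity(self, a, b):
        assert bic_bayes_factor(a, b) * bic_bayes_factor(b, a) == pytest.approx(1.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidParameterError):
            bic_bayes_factor(np.nan, 1.0)
        with pytest.raises(InvalidParameterError):
            bic_bayes_factor(1.0, np.inf)


class TestSequentialBf:
    def test_planted_group_effect_detected(self):
        table = generate_cohort(
            CohortParams(
                n_pd=150, n_hc=150,
                feature_effects={"beta_power": {"group": 0.8}},
                seed=11,
            )
        )
        result = sequential_bf(table, "beta_power")
        assert result.stats["group"].bf10 > 3
        assert "group" in result.flagged()

    def test_null_cohort_rarely_flags(self):
        flags = total = 0
        for seed in range(20):
            table = generate_cohort(CohortParams(n_pd=100, n_hc=100, seed=seed))
            result = sequential_bf(table, "beta_power")
            for stat in result.stats.values():
                total += 1
                flags += stat.bf10 > 3
        assert flags / total < 0.1

    def test_pure_noise_predictor_shrinks_evidence(self):
        # A predictor unrelated to the outcome loses to the BIC penalty.
        log_bfs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n = 100
            table = pd.DataFrame(
                {
                    "group": rng.permutation(["pd", "hc"] * (n // 2)),
                    "age": rng.uniform(50, 80, n),
                    "sex": rng.permutation(["female", "male"] * (n // 2)),
                    "cortical_thickness": rng.normal(2.5, 0.2, n),
                    "y": rng.normal(size=n),
                }
            )
            result = sequential_bf(table, "y", order=("group",))
            log_bfs.append(np.log(result.stats["group"].bf10))
        assert np.mean(log_bfs) < 0

    def test_full_model_coefficient_recovery(self):
        table = generate_cohort(
            CohortParams(
                n_pd=200, n_hc=200,
                feature_effects={"beta_power": {"group": 0.6}},
                noise_sd=0.05,
                seed=13,
            )
        )
        result = sequential_bf(table, "beta_power")
        stat = result.stats["group"]
        # outcome is z-scored, so the planted 0.6 shrinks by the outcome SD
        y = table["beta_power"].to_numpy()
        expected = 0.6 / y.std(ddof=0)
        assert stat.estimate == pytest.approx(expected, abs=0.05)
        assert stat.ci_low < stat.estimate < stat.ci_high

    def test_gaussian_bf_affine_invariant(self):
        table = small_cohort(seed=17)
        r1 = sequential_bf(table, "beta_power")
        table2 = table.copy()
        table2["beta_power"] = 7.0 * table2["beta_power"] - 3.0
        r2 = sequential_bf(table2, "beta_power")
        for name in r1.stats:
            assert r2.stats[name].bf10 == pytest.approx(r1.stats[name].bf10, rel=1e-9)

    def test_poisson_exposure_invariance(self):
        table = small_cohort(seed=19)
        r1 = sequential_bf(table, "burst_rate")
        table2 = table.copy()
        table2["analyzed_s"] = table2["analyzed_s"] * 2
        table2["n_events"] = table2["n_events"] * 2
        table2["burst_rate"] = table2["n_events"] / (table2["analyzed_s"] / 60.0)
        r2 = sequential_bf(table2, "burst_rate")
        for name in r1.stats:
            assert r2.stats[name].estimate == pytest.approx(
                r1.stats[name].estimate, abs=1e-6
            )


class TestPercentEffect:
    @staticmethod
    def make_result(coefs, family="poisson", order=("group", "age"), scales=None):
        names = ("intercept",) + order
        stats = {p: PredictorStat(0.0, 0.0, 0.0, 1.0) for p in order}
        return ModelComparisonResult(
            outcome="burst_rate", family=family, order=order, stats=stats,
            n=100, scales=scales or {"age_sd": 1.0, "age_mean": 65.0},
            coef_names=names, coefs=np.asarray(coefs, dtype=float),
            cov=np.eye(len(names)) * 1e-6,
        )

    def test_zero_coefficient_gives_zero_percent(self):
        result = self.make_result([1.0, 0.0, 0.0])
        pct, lo, hi = percent_effect(result, "group")
        assert pct == pytest.approx(0.0)

    def test_poisson_closed_form(self):
        result = self.make_result([1.0, 0.0, np.log(0.994)])
        pct, _, _ = percent_effect(result, "age")
        assert pct == pytest.approx(-0.6, abs=1e-12)

    def test_poisson_age_per_year_uses_scale(self):
        scales = {"age_sd": 10.0, "age_mean": 65.0}
        result = self.make_result([1.0, 0.0, 10 * np.log(0.994)], scales=scales)
        pct, _, _ = percent_effect(result, "age")
        assert pct == pytest.approx(-0.6, abs=1e-12)

    def test_unknown_predictor_rejected(self):
        result = self.make_result([1.0, 0.0, 0.0])
        with pytest.raises(InvalidParameterError):
            percent_effect(result, "thickness")

    def test_gaussian_nonpositive_control_mean_rejected(self):
        result = self.make_result(
            [0.0, 0.3, 0.0], family="gaussian",
            scales={"age_sd": 1.0, "age_mean": 65.0, "y_mean": -5.0, "y_sd": 1.0},
        )
        with pytest.raises(UndefinedPercentError):
            percent_effect(result, "group")

    def test_gaussian_percent_difference(self):
        table = generate_cohort(
            CohortParams(
                n_pd=300, n_hc=300,
                intercepts={"aperiodic_offset": 10.0},
                feature_effects={"aperiodic_offset": {"group": 2.4}},
                noise_sd=0.01,
                seed=23,
            )
        )
        result = sequential_bf(table, "aperiodic_offset")
        pct, lo, hi = percent_effect(result, "group", seed=1)
        assert pct == pytest.approx(24.0, abs=1.0)
        assert lo < pct < hi


class TestClinicalRegression:
    def test_planted_feature_effect_found(self):
        table = generate_cohort(
            CohortParams(
                n_pd=78, n_hc=2,
                clinical_effects={"upper_bradykinesia_contra": {"burst_rate": -0.8}},
                clinical_noise_sd=0.5,
                seed=29,
            )
        )
        result = clinical_regression(table, "upper_bradykinesia_contra")
        stat = result.stats["burst_rate"]
        assert stat.bf10 > 3
        assert stat.estimate < 0

    def test_noiseless_limit_null_predictors_vanish(self):
        table = generate_cohort(
            CohortParams(
                n_pd=78, n_hc=2,
                clinical_effects={"updrs3_total": {"burst_duration": 0.7}},
                clinical_noise_sd=1e-8,
                seed=31,
            )
        )
        result = clinical_regression(table, "updrs3_total")
        for name, stat in result.stats.items():
            if name == "burst_duration":
                assert abs(stat.estimate) > 0.9  # z-scored outcome, lone cause
            else:
                assert abs(stat.estimate) < 1e-5

    def test_insufficient_rows_raise(self):
        table = generate_cohort(CohortParams(n_pd=10, n_hc=2, seed=0))
        with pytest.raises(InsufficientDataError):
            clinical_regression(table, "updrs3_total")

    def test_null_symptom_calibration_smoke(self):
        flags = total = 0
        for seed in range(10):
            table = generate_cohort(CohortParams(n_pd=78, n_hc=2, seed=400 + seed))
            result = clinical_regression(table, "rest_tremor")
            for stat in result.stats.values():
                total += 1
                flags += stat.bf10 > 3
        assert flags / total < 0.1


class TestWelchT:
    def test_equal_means(self):
        t, df, p = welch_t_test(5.0, 1.0, 30, 5.0, 2.0, 40)
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_demographics_age_comparison(self):
        t, df, p = welch_t_test(65.6, 9.5, 78, 63.93, 8.4, 60)
        assert t == pytest.approx(1.09, abs=0.01)
        assert p == pytest.approx(0.28, abs=0.01)

    def test_pooled_limit_df(self):
        t, df, p = welch_t_test(1.0, 2.0, 25, 0.5, 2.0, 25)
        assert df == pytest.approx(48.0)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidParameterError):
            welch_t_test(1.0, 1.0, 1, 0.0, 1.0, 10)
        with pytest.raises(InvalidParameterError):
            welch_t_test(1.0, 0.0, 10, 0.0, 1.0, 10)


class TestYatesChiSquare:
    def test_group_by_sex_table(self):
        chi2, p = yates_chi_square([[29, 49], [27, 33]])
        assert round(chi2, 2) == 0.57
        assert round(p, 2) == 0.45

    def test_proportional_table_is_zero(self):
        chi2, p = yates_chi_square([[10, 20], [20, 40]])
        assert chi2 == 0.0
        assert p == pytest.approx(1.0)

    @given(
        a=st.integers(1, 200), b=st.integers(1, 200),
        c=st.integers(1, 200), d=st.integers(1, 200),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_textbook_formula(self, a, b, c, d):
        chi2, _ = yates_chi_square([[a, b], [c, d]])
        assert chi2 == pytest.approx(yates_chi2_textbook(a, b, c, d), abs=1e-10)

    def test_matches_scipy(self, rng):
        for _ in range(20):
            table = rng.integers(1, 100, size=(2, 2))
            chi2, p = yates_chi_square(table)
            ref = chi2_contingency(table, correction=True)
            assert chi2 == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_marginal_rejected(self):
        with pytest.raises(InvalidTableError):
            yates_chi_square([[0, 0], [5, 5]])


class TestDefaultOrder:
    def test_mains_precede_interactions(self):
        mains = DEFAULT_ORDER[:5]
        assert mains == ("group", "age", "age2", "sex", "thickness")
        assert all(":" in name for name in DEFAULT_ORDER[5:])
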