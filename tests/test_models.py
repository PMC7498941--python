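"""Mixed-model inference, effect sizes, and summary-statistic comparisons."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from netthin.models import (
    build_design,
    chi_square_2x2,
    demean,
    effect_size_from_t,
    fit_augmented_model,
    fit_lme,
    fit_primary_model,
    fit_stratified_model,
    pooled_two_sample_t,
    prepare_model_table,
)
from netthin.synth import CohortConfig, FixedEffects, generate_cohort

# printed (t, df, d) reporting triples of the emulated analyses; the t values
# are themselves rounded to 2-3 significant digits, so d is reproducible to
# one unit in the second decimal place
EFFECT_SIZE_TRIPLES = [
    (2.43, 421, 0.24),
    (4.08, 108, 0.78),
    (2.27, 421, 0.22),
    (2.48, 106, 0.48),
    (12.2, 107, 2.35),
    (2.36, 107, 0.46),
    (-3.73, 106, -0.73),
    (3.67, 106, 0.71),
    (1.36, 103, 0.27),
]


def _population_centered_table(cfg: CohortConfig) -> pd.DataFrame:
    """Model table centered at the generator's population means.

    In this parameterization the fitted fixed effects are directly
    comparable to the generative coefficients (empirical demeaning instead
    reparameterizes lower-order terms).
    """
    table, _ = generate_cohort(cfg)
    df = table.copy()
    df["fc"] = df["fc_true"]
    df["pib"] = df["pib_dvr"] - cfg.pib_population_mean
    df["age"] = df["age"] - cfg.baseline_age[0]
    df["education"] = df["education"] - cfg.education[0]
    return df


NONZERO_FE = FixedEffects(
    intercept=2.5, time=-0.02, fc=0.1, pib=-0.05, fc_pib=0.02,
    fc_time=0.03, pib_time=-0.018, fc_pib_time=0.2,
    age=-0.01, sex=0.05, education=0.002,
    age_time=-0.0005, sex_time=0.001, education_time=0.0002,
)


class TestEffectSize:
    @pytest.mark.parametrize("t,df,d", EFFECT_SIZE_TRIPLES)
    def test_reproduces_printed_triples(self, t, df, d):
        assert effect_size_from_t(t, df) == pytest.approx(d, abs=0.01)

    def test_zero_t_gives_zero(self):
        assert effect_size_from_t(0.0, 300) == 0.0

    def test_sign_preserved(self):
        assert effect_size_from_t(-2.0, 100) < 0

    def test_nonpositive_df_rejected(self):
        with pytest.raises(ValueError):
            effect_size_from_t(1.0, 0)


class TestPooledT:
    @pytest.mark.parametrize(
        "m1,s1,n1,m2,s2,n2,printed,digits",
        [
            (1.08, 0.1, 87, 1.46, 0.1, 33, 18.6, 1),
            (72.93, 6.3, 87, 74.5, 4.8, 33, 1.29, 2),
            (16.1, 3.0, 87, 16.6, 2.7, 33, 0.84, 2),
            (121.9, 8.0, 87, 122.9, 8.0, 33, 0.61, 2),
            (5.1, 0.8, 87, 4.9, 0.6, 33, 1.30, 2),
        ],
    )
    def test_reproduces_printed_group_statistics(self, m1, s1, n1, m2, s2, n2, printed, digits):
        out = pooled_two_sample_t(m1, s1, n1, m2, s2, n2)
        assert round(out.statistic, digits) == printed
        assert out.df == n1 + n2 - 2

    def test_equal_means_give_zero(self):
        assert pooled_two_sample_t(5.0, 1.0, 10, 5.0, 2.0, 12).statistic == 0.0

    def test_zero_variance_unequal_means_rejected(self):
        with pytest.raises(ValueError, match="infinite"):
            pooled_two_sample_t(1.0, 0.0, 10, 2.0, 0.0, 10)


class TestChiSquare:
    def test_proportional_table_gives_zero(self):
        assert chi_square_2x2([[20, 10], [40, 20]]).statistic == pytest.approx(0.0)

    def test_perfect_association(self):
        assert chi_square_2x2([[10, 0], [0, 10]]).statistic == pytest.approx(20.0)

    def test_matches_scipy_without_correction(self, rng):
        table = rng.integers(3, 40, size=(2, 2))
        out = chi_square_2x2(table)
        ref = chi2_contingency(table, correction=False)
        assert out.statistic == pytest.approx(ref.statistic)
        assert out.pvalue == pytest.approx(ref.pvalue)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2([[0, 0], [5, 3]])


class TestDemean:
    def test_example(self):
        np.testing.assert_allclose(demean([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0])

    def test_idempotent(self, rng):
        x = rng.normal(size=50)
        np.testing.assert_allclose(demean(demean(x)), demean(x), atol=1e-12)


class TestDesign:
    def test_primary_design_has_fourteen_terms(self):
        cfg = CohortConfig(n_subjects=12, seed=0)
        table, _ = generate_cohort(cfg)
        prep = prepare_model_table(table)
        assert build_design(prep, include_pib=True).shape[1] == 14

    def test_stratified_design_has_ten_terms(self):
        cfg = CohortConfig(n_subjects=12, seed=0)
        table, _ = generate_cohort(cfg)
        prep = prepare_model_table(table)
        assert build_design(prep, include_pib=False).shape[1] == 10

    @pytest.mark.parametrize("extras,added", [(("fpcn_fc",), 2), (("fpcn_ct",), 1),
                                              (("it_tau",), 2), (("fpcn_fc", "fpcn_ct", "it_tau"), 5)])
    def test_extra_blocks_add_expected_terms(self, rng, extras, added):
        cfg = CohortConfig(n_subjects=12, seed=0)
        table, _ = generate_cohort(cfg)
        for c in ("fpcn_fc", "fpcn_ct", "it_tau"):
            table[c] = rng.normal(size=len(table))
        prep = prepare_model_table(table, extra_cols=("fpcn_fc", "fpcn_ct", "it_tau"))
        base = build_design(prep, include_pib=False).shape[1]
        assert build_design(prep, include_pib=False, extras=extras).shape[1] == base + added

    def test_residual_df_is_rows_minus_fixed_effects(self):
        cfg = CohortConfig(n_subjects=30, seed=3)
        table, _ = generate_cohort(cfg)
        prep = prepare_model_table(table)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_primary_model(prep)
        assert fit.params["df"].iloc[0] == len(prep) - 14


class TestLmeFits:
    def test_noiseless_cohort_recovers_every_fixed_effect(self):
        cfg = CohortConfig(n_subjects=40, random_intercept_sd=0, random_slope_sd=0,
                           residual_sd=0, fixed_effects=NONZERO_FE, seed=5)
        df = _population_centered_table(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_lme(df, build_design(df, include_pib=True), "fc:pib:time")
        fe = cfg.fixed_effects
        expected = {
            "Intercept": fe.intercept, "fc": fe.fc, "pib": fe.pib, "time": fe.time,
            "fc:pib": fe.fc_pib, "fc:time": fe.fc_time, "pib:time": fe.pib_time,
            "fc:pib:time": fe.fc_pib_time, "age": fe.age, "sex": fe.sex,
            "education": fe.education, "age:time": fe.age_time,
            "sex:time": fe.sex_time, "education:time": fe.education_time,
        }
        for term, val in expected.items():
            assert fit.params.loc[term, "estimate"] == pytest.approx(val, abs=1e-6)

    def test_planted_negative_interaction_recovered_with_significance(self):
        fe = dataclasses.replace(CohortConfig().fixed_effects, fc_pib_time=-0.4)
        cfg = CohortConfig(n_subjects=120, fixed_effects=fe, seed=8)
        table, _ = generate_cohort(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_primary_model(prepare_model_table(table))
        row = fit.primary
        assert row["estimate"] < 0
        assert row["estimate"] + 1.96 * row["se"] < 0  # CI excludes zero

    def test_mixed_model_matches_ols_when_random_effects_vanish(self):
        cfg = CohortConfig(n_subjects=200, random_intercept_sd=0, random_slope_sd=0,
                           residual_sd=0.01, fixed_effects=NONZERO_FE, seed=12)
        df = _population_centered_table(cfg)
        design = build_design(df, include_pib=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_lme(df, design, "fc:pib:time")
        beta_ols, *_ = np.linalg.lstsq(design.to_numpy(), df["thickness"].to_numpy(), rcond=None)
        np.testing.assert_allclose(fit.params["estimate"].to_numpy(), beta_ols, atol=1e-3)

    def test_effect_only_in_high_amyloid_stratum(self):
        # connectivity slows thinning only among high-amyloid subjects: the
        # FC:time term must be significant in the high stratum, null in low
        base = CohortConfig().fixed_effects
        high_fe = dataclasses.replace(base, fc_time=0.15, fc_pib_time=0.0, pib_time=0.0)
        low_fe = dataclasses.replace(base, fc_time=0.0, fc_pib_time=0.0, pib_time=0.0)
        high_cfg = CohortConfig(n_subjects=60, fixed_effects=high_fe,
                                pib_weights=(0.0, 1.0), seed=21)
        low_cfg = CohortConfig(n_subjects=100, fixed_effects=low_fe,
                               pib_weights=(1.0, 0.0), seed=22)
        high, _ = generate_cohort(high_cfg)
        low, _ = generate_cohort(low_cfg)
        low["subject"] = "L" + low["subject"]
        table = pd.concat([high, low], ignore_index=True)
        table["amyloid_group"] = np.where(table["pib_dvr"] > 1.186, "high", "low")
        prep = prepare_model_table(table)
        prep["amyloid_group"] = table["amyloid_group"].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_high = fit_stratified_model(prep, "high")
            fit_low = fit_stratified_model(prep, "low")
        assert fit_high.primary["pvalue"] < 0.01
        assert fit_high.primary["estimate"] > 0
        assert fit_low.primary["pvalue"] > 0.05

    def test_orthogonal_augmentation_leaves_primary_term(self, rng):
        cfg = CohortConfig(n_subjects=60, random_intercept_sd=0, random_slope_sd=0,
                           residual_sd=1e-5, fixed_effects=NONZERO_FE, seed=31)
        df = _population_centered_table(cfg)
        df["amyloid_group"] = "high"
        extra = rng.normal(size=len(df))
        design = build_design(df, include_pib=False).to_numpy()
        extra = extra - design @ np.linalg.lstsq(design, extra, rcond=None)[0]
        df["fpcn_ct"] = extra  # exactly uncorrelated with every predictor
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            plain = fit_stratified_model(df, "high")
            aug = fit_augmented_model(df, ("fpcn_ct",), group="high")
        assert aug.params.loc["fc:time", "estimate"] == pytest.approx(
            plain.params.loc["fc:time", "estimate"], abs=1e-6
        )

    def test_collinear_augmentation_inflates_standard_errors(self, rng):
        cfg = CohortConfig(n_subjects=60, seed=33)
        table, _ = generate_cohort(cfg)
        table["amyloid_group"] = "high"
        table["fpcn_fc"] = table["fc_true"] + rng.normal(0, 0.005, size=len(table))
        prep = prepare_model_table(table, extra_cols=("fpcn_fc",))
        prep["amyloid_group"] = "high"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            plain = fit_stratified_model(prep, "high")
            aug = fit_augmented_model(prep, ("fpcn_fc",), group="high")
        assert aug.params.loc["fc:time", "se"] > 2 * plain.params.loc["fc:time", "se"]

    def test_all_three_augmentation_reports_every_term(self, rng):
        cfg = CohortConfig(n_subjects=40, seed=35)
        table, _ = generate_cohort(cfg)
        for c in ("fpcn_fc", "fpcn_ct", "it_tau"):
            table[c] = rng.normal(size=len(table))
        prep = prepare_model_table(table, extra_cols=("fpcn_fc", "fpcn_ct", "it_tau"))
        prep["amyloid_group"] = "high"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_augmented_model(prep, ("fpcn_fc", "fpcn_ct", "it_tau"), group="high")
        for term in ("fpcn_fc", "fpcn_fc:time", "fpcn_ct", "it_tau", "it_tau:time"):
            assert term in fit.params.index
        assert fit.params["df"].iloc[0] == fit.n_obs - 15

    def test_missing_group_column_rejected(self):
        cfg = CohortConfig(n_subjects=12, seed=0)
        table, _ = generate_cohort(cfg)
        prep = prepare_model_table(table)
        with pytest.raises(ValueError, match="amyloid_group"):
            fit_stratified_model(prep, "high")
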