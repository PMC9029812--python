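import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr, ttest_ind

from metclass.containers import ConfigError
from metclass import synthetic_data as syn


class TestGenerateCohort:
    def test_study_scale_group_sizes(self):
        cfg = syn.GeneratorConfig(seed=1)
        cohort = syn.generate_cohort(cfg)
        assert len(cohort) == 198
        counts = cohort["phenotype"].value_counts()
        assert counts["Control"] == 85
        assert counts["AD"] == 57
        assert counts["PD"] == 56

    def test_control_age_mean_within_clt_bound(self):
        cohort = syn.generate_cohort(syn.GeneratorConfig(seed=1))
        ages = cohort.loc[cohort["phenotype"] == "Control", "age"]
        assert abs(ages.mean() - 53.7) < 20.3 * 3 / np.sqrt(85)
        assert ages.between(20, 90).all()

    def test_run_index_is_permutation(self):
        cohort = syn.generate_cohort(syn.GeneratorConfig(seed=3))
        assert sorted(cohort["run_index"]) == list(range(1, 199))

    def test_round_robin_batches_forced(self):
        cfg = syn.GeneratorConfig(n_per_group=(2, 2, 2), batch_size=3, seed=0)
        cohort = syn.generate_cohort(cfg)
        sizes = cohort["batch"].value_counts()
        assert set(sizes.index) == {1, 2}
        assert (sizes == 3).all()

    def test_batch_sizes_differ_by_at_most_one(self):
        cohort = syn.generate_cohort(syn.GeneratorConfig(seed=5))
        sizes = cohort["batch"].value_counts()
        assert sizes.max() - sizes.min() <= 1

    def test_ledd_and_gba_only_for_pd(self):
        cohort = syn.generate_cohort(syn.GeneratorConfig(seed=2))
        pd_rows = cohort["phenotype"] == "PD"
        assert cohort.loc[pd_rows, "ledd"].notna().all()
        assert (cohort.loc[pd_rows, "ledd"] >= 0).all()
        assert cohort.loc[~pd_rows, "ledd"].isna().all()

    def test_nonpositive_group_size_rejected(self):
        with pytest.raises(ConfigError):
            syn.GeneratorConfig(n_per_group=(0, 10, 10))
        with pytest.raises(ConfigError):
            syn.GeneratorConfig(n_per_group=(1, 10, 10))

    def test_seeded_generation_is_reproducible(self):
        a = syn.generate_cohort(syn.GeneratorConfig(seed=11))
        b = syn.generate_cohort(syn.GeneratorConfig(seed=11))
        pd.testing.assert_frame_equal(a, b)


class TestGenerateProfiles:
    def test_pure_noise_variance_near_one(self):
        cfg = syn.GeneratorConfig(
            n_per_group=(40, 40, 2), n_features=200, n_signal_features=0,
            effect_size=0.0, age_effect_sd=0.0, sex_effect_sd=0.0,
            drift_amplitude=0.0, seed=4,
        )
        cohort = syn.generate_cohort(cfg)
        fm, _ = syn.generate_profiles(cohort, cfg)
        assert abs(fm.values.var(axis=0, ddof=1).mean() - 1.0) < 0.05

    def test_signal_features_have_larger_t_statistics(self):
        cfg = syn.GeneratorConfig(
            n_per_group=(30, 30, 2), n_features=500, n_signal_features=10,
            effect_size=1.5, drift_amplitude=0.0, seed=1,
        )
        cohort = syn.generate_cohort(cfg)
        fm, ann = syn.generate_profiles(cohort, cfg)
        g = cohort["phenotype"].to_numpy()
        a, c = fm.values[g == "AD"], fm.values[g == "Control"]
        t = np.abs(ttest_ind(a, c, axis=0).statistic)
        is_sig = np.array([x.is_signal for x in ann])
        assert np.all(t[is_sig] > np.median(t[~is_sig]))

    def test_linear_drift_correlates_with_run_order(self):
        cfg = syn.GeneratorConfig(
            n_per_group=(40, 40, 2), n_features=30, n_signal_features=0,
            effect_size=0.0, drift_amplitude=2.0, drift_form="linear", seed=1,
        )
        cohort = syn.generate_cohort(cfg)
        fm, _ = syn.generate_profiles(cohort, cfg)
        run = cohort["run_index"].to_numpy()
        rho = np.array([abs(spearmanr(fm.values[:, j], run).statistic)
                        for j in range(fm.n_features)])
        assert np.mean(rho > 0.6) > 0.8

    @pytest.mark.parametrize("form", ["step", "smooth"])
    def test_nonlinear_drift_inflates_feature_variance(self, form):
        # step/sine drift is not monotone in run order, so the diagnostic
        # is added variance (amplitude 2 on unit noise) rather than rank
        # correlation
        cfg = syn.GeneratorConfig(
            n_per_group=(40, 40, 2), n_features=30, n_signal_features=0,
            effect_size=0.0, age_effect_sd=0.0, sex_effect_sd=0.0,
            drift_amplitude=2.0, drift_form=form, seed=1,
        )
        cohort = syn.generate_cohort(cfg)
        fm, _ = syn.generate_profiles(cohort, cfg)
        var = fm.values.var(axis=0, ddof=1)
        assert np.median(var) > 2.0  # unit noise plus drift power

    def test_empty_cohort_rejected(self):
        cfg = syn.GeneratorConfig(n_per_group=(5, 5, 5), n_features=10)
        with pytest.raises(ConfigError):
            syn.generate_profiles(pd.DataFrame(columns=["subject_id"]), cfg)

    def test_latent_mode_correlates_signal_features(self):
        cfg = syn.GeneratorConfig(
            n_per_group=(40, 40, 2), n_features=100, n_signal_features=10,
            effect_size=1.5, signal_mode="latent", n_secondary_features=30,
            drift_amplitude=0.0, seed=9,
        )
        cohort = syn.generate_cohort(cfg)
        fm, ann = syn.generate_profiles(cohort, cfg)
        sig = fm.values[:, :10]
        corr = np.corrcoef(sig.T)
        off = corr[np.triu_indices(10, 1)]
        assert off.mean() > 0.4  # loadings 0.8 -> pairwise ~0.64


class TestInjectMissingness:
    def test_rate_zero_masks_nothing(self, small_study):
        cfg = syn.GeneratorConfig(
            n_per_group=(5, 5, 5), n_features=20, missing_mechanism="MCAR",
            missing_rates=0.0, seed=0,
        )
        cohort = syn.generate_cohort(cfg)
        fm, _ = syn.generate_profiles(cohort, cfg)
        out = syn.inject_missingness(fm, cohort, cfg)
        assert out.mask.all()

    def test_mcar_realized_rate_close_to_target(self):
        cfg = syn.GeneratorConfig(
            n_per_group=(85, 57, 56), n_features=1000,
            missing_mechanism="MCAR", missing_rates=0.16, seed=8,
        )
        cohort = syn.generate_cohort(cfg)
        fm, _ = syn.generate_profiles(cohort, cfg)
        out = syn.inject_missingness(fm, cohort, cfg)
        assert 0.14 <= out.overall_missing_fraction() <= 0.18

    def test_mnar_phenotype_rate_ordering(self):
        cfg = syn.GeneratorConfig(
            n_per_group=(40, 40, 40), n_features=300,
            missing_mechanism="MNAR-phenotype",
            missing_rates=(0.5, 0.5, 0.2), seed=6,
        )
        cohort = syn.generate_cohort(cfg)
        fm, _ = syn.generate_profiles(cohort, cfg)
        out = syn.inject_missingness(fm, cohort, cfg)
        g = cohort["phenotype"].to_numpy()
        rates = {ph: 1 - out.mask[g == ph].mean() for ph in ("Control", "AD", "PD")}
        assert abs(rates["Control"] - rates["AD"]) < 0.05
        assert rates["Control"] > rates["PD"] + 0.2

    def test_mnar_abundance_left_censors(self):
        cfg = syn.GeneratorConfig(
            n_per_group=(30, 30, 2), n_features=50,
            missing_mechanism="MNAR-abundance", missing_rates=0.3, seed=2,
        )
        cohort = syn.generate_cohort(cfg)
        fm, _ = syn.generate_profiles(cohort, cfg)
        out = syn.inject_missingness(fm, cohort, cfg)
        for j in range(out.n_features):
            masked_vals = fm.values[~out.mask[:, j], j]
            kept_vals = fm.values[out.mask[:, j], j]
            assert masked_vals.max() < kept_vals.min()

    def test_mar_missingness_tracks_age(self):
        from scipy.stats import spearmanr
        cfg = syn.GeneratorConfig(
            n_per_group=(50, 50, 2), n_features=200,
            missing_mechanism="MAR", missing_rates=0.3, seed=4,
        )
        cohort = syn.generate_cohort(cfg)
        fm, _ = syn.generate_profiles(cohort, cfg)
        out = syn.inject_missingness(fm, cohort, cfg)
        row_missing = 1 - out.mask.mean(axis=1)
        rho = spearmanr(cohort["age"], row_missing).statistic
        assert rho < -0.5  # older subjects are more complete by design

    def test_incomplete_input_rejected(self, small_study):
        with pytest.raises(ValueError):
            syn.inject_missingness(small_study["observed"],
                                   small_study["cohort"], small_study["cfg"])


class TestCohortBalance:
    def test_equal_sex_ratios_give_null_chi2(self):
        cohort = pd.DataFrame({
            "phenotype": ["Control"] * 10 + ["AD"] * 10,
            "sex": (["F"] * 5 + ["M"] * 5) * 2,
            "age": np.r_[np.full(10, 60.0), np.full(10, 62.0)],
        })
        rep = syn.cohort_balance_tests(cohort)
        chi2, dof, p = rep["chi2_sex_phenotype"]
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_two_by_two_independence(self):
        chi2, dof, p = syn.sex_phenotype_chi2([[10, 10], [10, 10]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_single_group_rejected(self):
        cohort = pd.DataFrame({
            "phenotype": ["AD"] * 6, "sex": ["F", "M"] * 3,
            "age": np.linspace(60, 70, 6),
        })
        with pytest.raises(ValueError):
            syn.cohort_balance_tests(cohort)

    def test_anova_reports_degrees_of_freedom(self):
        cohort = syn.generate_cohort(syn.GeneratorConfig(seed=1))
        rep = syn.cohort_balance_tests(cohort)
        f, df1, df2, p = rep["anova_age_phenotype"]
        assert (df1, df2) == (2, 195)
        assert p < 0.05  # configured age gaps are large


def test_generate_study_reproducible(small_study):
    cfg = small_study["cfg"]
    cohort2, observed2, _, _ = syn.generate_study(cfg)
    pd.testing.assert_frame_equal(small_study["cohort"], cohort2)
    np.testing.assert_array_equal(small_study["observed"].mask, observed2.mask)
    np.testing.assert_allclose(
        np.nan_to_num(small_study["observed"].values),
        np.nan_to_num(observed2.values))


def test_study_csv_round_trip(tmp_path, small_study):
    from metclass.containers import FeatureMatrix
    syn.write_study(tmp_path, small_study["cohort"], small_study["observed"],
                    small_study["annotations"])
    back = FeatureMatrix.from_csv(tmp_path / "matrix.csv")
    np.testing.assert_array_equal(back.mask, small_study["observed"].mask)
    np.testing.assert_allclose(np.nan_to_num(back.values),
                               np.nan_to_num(small_study["observed"].values))
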