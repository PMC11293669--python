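"""Synthetic cohort generator and known-quantile oracle problems."""

import numpy as np
import pandas as pd
import pytest

import painpi as pp
from painpi.synthetic import feature_columns


class TestCohortGenerator:
    def test_same_seed_is_bit_identical(self):
        cfg = pp.CohortConfig(n_subjects=10, obs_per_subject_level=3, seed=7)
        a, b = pp.generate_cohort(cfg), pp.generate_cohort(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        a = pp.generate_cohort(pp.CohortConfig(n_subjects=10,
                                               obs_per_subject_level=3, seed=1))
        b = pp.generate_cohort(pp.CohortConfig(n_subjects=10,
                                               obs_per_subject_level=3, seed=2))
        assert not np.allclose(a[feature_columns()].to_numpy(),
                               b[feature_columns()].to_numpy())

    def test_row_count_and_cleaning_scale(self):
        # 87 x 5 x 20 = 8700 rows before cleaning; ~1% carry a missing
        # cell, so the cleaned table sits near 8612 rows
        cfg = pp.CohortConfig(seed=3)
        table = pp.generate_cohort(cfg)
        assert len(table) == 8700
        clean = pp.clean_table(table)
        assert 8500 <= len(clean) < 8700
        assert clean[feature_columns()].notna().all().all()

    def test_labels_and_cluster_truth(self, small_cohort):
        y = small_cohort["pain_label"]
        assert y.between(0, 4).all()
        assert set(small_cohort["cluster_truth"].astype(int)) == {0, 1, 2, 3}
        # balanced subject assignment across the 4 planted clusters
        sizes = (small_cohort.drop_duplicates("subject_id")
                 .groupby("cluster_truth", observed=True).size())
        assert sizes.min() >= 2

    def test_integer_levels_without_jitter(self):
        cfg = pp.CohortConfig(n_subjects=6, obs_per_subject_level=2,
                              label_jitter=0.0, missing_rate=0.0, seed=0)
        t = pp.generate_cohort(cfg)
        assert set(t["pain_label"]) == {0.0, 1.0, 2.0, 3.0, 4.0}

    def test_degenerate_generator_collapses_within_cluster(self):
        cfg = pp.CohortConfig(n_subjects=8, obs_per_subject_level=2,
                              effect_size=0.0, subject_sd=0.0,
                              noise_sd_base=1e-12, subject_noise_sd=0.0,
                              response_noise_sd=0.0, heteroscedasticity=0.0,
                              missing_rate=0.0, label_jitter=0.0, seed=5)
        t = pp.generate_cohort(cfg)
        for _, grp in t.groupby("cluster_truth", observed=True):
            X = grp[feature_columns()].to_numpy()
            assert np.allclose(X, X[0], atol=1e-6)

    def test_heteroscedastic_noise_schedule(self):
        # empirical per-level feature noise sd tracks
        # noise_sd_base * (1 + h * level) within 5% at large samples
        h, base = 0.4, 0.5
        cfg = pp.CohortConfig(n_subjects=5, obs_per_subject_level=400,
                              effect_size=0.0, subject_sd=0.0, cluster_sd=0.0,
                              noise_sd_base=base, heteroscedasticity=h,
                              subject_noise_sd=0.0, response_noise_sd=0.0,
                              noise_df=np.inf, missing_rate=0.0,
                              label_jitter=0.0, seed=9)
        t = pp.generate_cohort(cfg)
        lvl = t["pain_label"].astype(int)
        for level in range(5):
            sd = t.loc[lvl == level, feature_columns()].to_numpy().std()
            assert sd == pytest.approx(base * (1 + h * level), rel=0.05)

    def test_missingness_rate(self):
        cfg = pp.CohortConfig(n_subjects=40, obs_per_subject_level=10,
                              missing_rate=0.05, seed=21)
        t = pp.generate_cohort(cfg)
        frac = t[feature_columns()].isna().any(axis=1).mean()
        assert frac == pytest.approx(0.05, abs=0.01)

    @pytest.mark.parametrize("bad", [
        dict(n_subjects=0), dict(noise_sd_base=0.0), dict(missing_rate=1.5),
        dict(subject_sd=-1.0), dict(n_latent_clusters=0), dict(noise_df=2.0),
        dict(n_levels=4),
    ])
    def test_invalid_config_raises(self, bad):
        with pytest.raises(ValueError):
            pp.CohortConfig(**bad)

    def test_config_yaml_json_roundtrip(self, tmp_path):
        cfg = pp.CohortConfig(n_subjects=9, seed=4)
        for name in ("c.yaml", "c.json"):
            cfg.save(tmp_path / name)
            assert pp.CohortConfig.load(tmp_path / name) == cfg

    def test_csv_roundtrip(self, tmp_path, small_cohort):
        path = tmp_path / "cohort.csv"
        pp.write_feature_table(small_cohort, path)
        back = pp.read_feature_table(path)
        np.testing.assert_allclose(back[feature_columns()].to_numpy(),
                                   small_cohort[feature_columns()].to_numpy())


class TestKnownQuantileRegression:
    def test_gaussian_oracle_width_is_closed_form(self):
        df = pp.generate_known_quantile_regression(100, sigma=1.0,
                                                   alpha=0.05, seed=0)
        widths = df["oracle_upper"] - df["oracle_lower"]
        assert np.allclose(widths, 2 * 1.959964 * 1.0, atol=1e-4)

    def test_oracle_coverage_near_nominal(self):
        df = pp.generate_known_quantile_regression(10_000, alpha=0.05, seed=1)
        covered = ((df["oracle_lower"] <= df["y"])
                   & (df["y"] <= df["oracle_upper"])).mean()
        assert 0.94 <= covered <= 0.96

    def test_heteroscedastic_oracle_coverage(self):
        df = pp.generate_known_quantile_regression(
            10_000, noise="heteroscedastic", alpha=0.1, seed=2)
        covered = ((df["oracle_lower"] <= df["y"])
                   & (df["y"] <= df["oracle_upper"])).mean()
        # binomial 99% band around 0.9 at n = 10000
        half = 2.58 * np.sqrt(0.9 * 0.1 / 10_000)
        assert abs(covered - 0.9) < half + 0.005

    def test_zero_noise_limit(self):
        df = pp.generate_known_quantile_regression(50, sigma=1e-12, seed=3)
        assert (df["oracle_upper"] - df["oracle_lower"]).max() < 1e-9

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            pp.generate_known_quantile_regression(5, seed=0)
        with pytest.raises(ValueError):
            pp.generate_known_quantile_regression(100, noise="laplace", seed=0)
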