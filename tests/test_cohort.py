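import numpy as np
import pandas as pd
import pytest

from exglyc.cohort import (
    CohortConfig,
    add_measurement_noise,
    apply_outcome_model,
    generate_cohort,
    generate_sessions,
    generate_subjects,
    read_session_csv,
    sessions_to_csv,
    prospective_cohort_config,
)
from exglyc.features import transform_minutes, postprandial_flag


class TestGenerateSubjects:
    def test_zero_subjects_gives_empty_table(self):
        assert len(generate_subjects(CohortConfig(n_subjects=0))) == 0

    def test_identical_seed_identical_output(self):
        cfg = CohortConfig(n_subjects=30, seed=9)
        pd.testing.assert_frame_equal(
            generate_subjects(cfg), generate_subjects(CohortConfig(n_subjects=30, seed=9))
        )

    def test_covariate_moments_match_configuration(self):
        cfg = CohortConfig(n_subjects=5000, seed=1)
        s = generate_subjects(cfg)
        se_age = cfg.age_sd / np.sqrt(5000)
        assert abs(s["age"].mean() - cfg.age_mean) < 3 * se_age
        se_a1c = cfg.hba1c_sd / np.sqrt(5000)
        # HbA1c truncation at 3 barely shifts the mean at these settings
        assert abs(s["hba1c"].mean() - cfg.hba1c_mean) < 3 * se_a1c + 0.02
        assert (s["hba1c"] > 3).all()
        p = cfg.p_male
        assert abs((s["sex"] == "male").mean() - p) < 3 * np.sqrt(p * (1 - p) / 5000)

    def test_random_effects_have_configured_covariance(self):
        cfg = CohortConfig(n_subjects=5000, seed=3)
        s = generate_subjects(cfg)
        cov = np.cov(s["random_intercept"], s["random_slope"])
        assert cov[0, 0] == pytest.approx(cfg.intercept_sd**2, rel=0.15)
        assert cov[1, 1] == pytest.approx(cfg.slope_sd**2, rel=0.15)
        corr = cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1])
        assert corr == pytest.approx(cfg.intercept_slope_corr, abs=0.05)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(p_male=1.5)
        with pytest.raises(ValueError):
            CohortConfig(residual_sd=-1.0)
        with pytest.raises(ValueError):
            CohortConfig(intercept_slope_corr=-2.0)


class TestGenerateSessions:
    def test_session_numbers_consecutive(self):
        cfg = CohortConfig(n_subjects=1, sessions_per_subject=3, seed=0)
        sess = generate_sessions(generate_subjects(cfg), cfg)
        assert list(sess["session_number"]) == [1, 2, 3]

    def test_pure_postprandial_mixture(self):
        cfg = CohortConfig(n_subjects=5, sessions_per_subject=10, seed=0,
                           p_postprandial=1.0)
        sess = generate_sessions(generate_subjects(cfg), cfg)
        assert (sess["minutes_since_meal"] <= 120).all()

    def test_postprandial_fraction_matches_weight(self):
        cfg = CohortConfig(n_subjects=500, sessions_per_subject=10, seed=2)
        sess = generate_sessions(generate_subjects(cfg), cfg)
        frac = (sess["minutes_since_meal"] <= 120).mean()
        se = np.sqrt(0.8 * 0.2 / len(sess))
        assert abs(frac - cfg.p_postprandial) < 3 * se

    def test_empty_subjects_rejected(self):
        cfg = CohortConfig(n_subjects=0)
        with pytest.raises(ValueError):
            generate_sessions(generate_subjects(cfg), cfg)

    def test_pre_glucose_floor(self):
        cfg = CohortConfig(n_subjects=100, sessions_per_subject=5, seed=0,
                           glucose_mean_mean=2.5, glucose_mean_sd=0.3,
                           glucose_sd_mean=2.0)
        sess = generate_sessions(generate_subjects(cfg), cfg)
        assert (sess["pre_glucose"] > 0.5).all()


class TestOutcomeModel:
    def test_noiseless_outcome_is_exact_linear_function(self):
        cfg = CohortConfig(n_subjects=6, sessions_per_subject=4, seed=5,
                           intercept_sd=0.0, slope_sd=0.0, residual_sd=0.0)
        subjects = generate_subjects(cfg)
        sessions = apply_outcome_model(generate_sessions(subjects, cfg), subjects, cfg)
        m = sessions.merge(subjects, on="subject_id")
        beta = cfg.beta
        eta = (
            beta["intercept"]
            + beta["pre_glucose"] * m["pre_glucose"]
            + beta["minutes_since_meal"] * m["minutes_since_meal"]
            + beta["nl_minutes"] * transform_minutes(m["minutes_since_meal"].to_numpy(), cfg.t_max)
            + beta["postprandial"] * postprandial_flag(m["minutes_since_meal"].to_numpy())
            + beta["hba1c"] * m["hba1c"]
            + beta["duration"] * m["duration"]
            + beta["pct_aamhr"] * m["pct_aamhr"]
            + beta["sulfonylurea"] * m["sulfonylurea"]
            + beta["age"] * m["age"]
            + beta["session_number"] * m["session_number"]
            + beta["sex"] * (m["sex"] == "male")
            + beta["metformin"] * m["metformin"]
        )
        delta = sessions["post_glucose"] - sessions["pre_glucose"]
        assert np.allclose(delta, eta, atol=1e-10)

    def test_null_model_preserves_pre_glucose(self):
        cfg = CohortConfig(n_subjects=4, sessions_per_subject=3, seed=5,
                           beta={"intercept": 0.0}, intercept_sd=0.0,
                           slope_sd=0.0, residual_sd=0.0)
        subjects = generate_subjects(cfg)
        sessions = apply_outcome_model(generate_sessions(subjects, cfg), subjects, cfg)
        assert np.allclose(sessions["post_glucose"], sessions["pre_glucose"])

    def test_generative_slope_recovered_by_regression(self):
        # regress delta on pre_glucose with all other covariates held at
        # constants: the slope must recover the configured coefficient
        cfg = CohortConfig(n_subjects=1000, sessions_per_subject=10, seed=8,
                           intercept_sd=0.0, slope_sd=0.0,
                           minutes_postprandial_range=(60.0, 60.0001),
                           p_postprandial=1.0, duration_sd=0.0,
                           pct_aamhr_sd=0.0)
        subjects = generate_subjects(cfg)
        sessions = apply_outcome_model(generate_sessions(subjects, cfg), subjects, cfg)
        delta = (sessions["post_glucose"] - sessions["pre_glucose"]).to_numpy()
        keep = sessions["post_glucose"] > 0.31  # outside the physiological floor
        x = sessions["pre_glucose"].to_numpy()[keep]
        d = delta[keep]
        X = np.column_stack([np.ones(len(x)), x])
        coef, *_ = np.linalg.lstsq(X, d, rcond=None)
        resid = d - X @ coef
        se = np.sqrt(resid.var() / (len(x) * x.var()))
        assert abs(coef[1] - cfg.beta["pre_glucose"]) < 3 * se

    def test_missing_covariate_names_the_session(self):
        cfg = CohortConfig(n_subjects=3, sessions_per_subject=2, seed=0)
        subjects = generate_subjects(cfg)
        sessions = generate_sessions(subjects, cfg)
        sessions.loc[3, "duration"] = np.nan
        with pytest.raises(ValueError, match="duration"):
            apply_outcome_model(sessions, subjects, cfg)


class TestMeasurementNoise:
    def test_switch_off_is_identity(self, small_cohort):
        _, sessions = small_cohort
        cfg = CohortConfig(measurement_noise="off")
        assert add_measurement_noise(sessions, cfg) is sessions

    def test_relative_band_bounds(self):
        cfg = CohortConfig(n_subjects=2, sessions_per_subject=5, seed=0,
                           measurement_noise="iso_band")
        sessions = pd.DataFrame(
            dict(subject_id=["A"] * 2000, session_number=np.arange(2000) + 1,
                 pre_glucose=10.0, post_glucose=10.0,
                 minutes_since_meal=60.0, duration=40.0, pct_aamhr=70.0)
        )
        noisy = add_measurement_noise(sessions, cfg)
        for col in ("pre_glucose", "post_glucose"):
            assert noisy[col].between(8.0, 12.0).all()
            # uniform band: endpoints approached
            assert noisy[col].max() > 11.8 and noisy[col].min() < 8.2

    def test_hypoglycemic_band_is_absolute(self):
        cfg = CohortConfig(seed=1, measurement_noise="iso_band")
        sessions = pd.DataFrame(
            dict(subject_id=["A"] * 10000, session_number=np.arange(10000) + 1,
                 pre_glucose=4.0, post_glucose=4.0,
                 minutes_since_meal=60.0, duration=40.0, pct_aamhr=70.0)
        )
        noisy = add_measurement_noise(sessions, cfg)
        assert noisy["post_glucose"].between(3.17, 4.83).all()
        assert noisy["post_glucose"].max() > 4.80
        assert noisy["post_glucose"].min() < 3.20


class TestCohortRoundTrip:
    def test_full_cohort_deterministic(self):
        a = generate_cohort(CohortConfig(n_subjects=10, seed=4))
        b = generate_cohort(CohortConfig(n_subjects=10, seed=4))
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_csv_round_trip(self, tmp_path, small_cohort):
        subjects, sessions = small_cohort
        path = tmp_path / "sessions.csv"
        sessions_to_csv(sessions, subjects, path)
        subj2, sess2 = read_session_csv(path)
        assert len(sess2) == len(sessions)
        assert set(subj2["subject_id"]) == set(subjects["subject_id"])
        assert np.allclose(sess2["pre_glucose"], sessions["pre_glucose"])

    def test_mgdl_units_rejected(self, tmp_path):
        cfg = CohortConfig(n_subjects=3, sessions_per_subject=2, seed=0,
                           glucose_mean_mean=170.0, glucose_mean_sd=1.0)
        subjects, sessions = generate_cohort(cfg)
        path = tmp_path / "bad.csv"
        sessions_to_csv(sessions, subjects, path)
        with pytest.raises(ValueError, match="mg/dL"):
            read_session_csv(path)

    def test_yaml_config_round_trip(self, tmp_path):
        cfg = prospective_cohort_config(seed=3)
        p = tmp_path / "cohort.yaml"
        cfg.to_yaml(p)
        cfg2 = CohortConfig.from_yaml(p)
        assert cfg2 == cfg
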