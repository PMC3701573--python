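"""Seeded synthetic cohort of type 2 diabetes subjects and exercise sessions.

The generator emulates the statistical structure of a pooled exercise-trial
cohort: subject-level covariates (age, sex, HbA1c, oral-medication status,
habitual pre-exercise glycemia) drawn from configured marginals, repeated
exercise sessions per subject, and a mixed-effects outcome model for the
acute glucose change

    delta_i,j = x_ij' beta + b0_i + b1_i * pre_glucose_ij + eps_ij

with subject random intercept b0 (mmol/L) and random slope b1 on
pre-exercise glucose, so every downstream stage (selection, importance,
structure testing, validation) is exercisable without trial data.  It
reproduces statistical structure only — no physiological glucose dynamics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .features import transform_minutes, postprandial_flag

logger = logging.getLogger(__name__)

SESSION_CSV_COLUMNS = [
    "subject_id",
    "session_number",
    "age",
    "sex",
    "hba1c",
    "metformin",
    "sulfonylurea",
    "pre_glucose",
    "post_glucose",
    "minutes_since_meal",
    "duration",
    "pct_aamhr",
]

#: Fixed-effect coefficients of the generative outcome model (mmol/L per
#: unit of each predictor).  The %AAMHR coefficient is per percentage point.
DEFAULT_BETA = {
    "intercept": 0.0,
    "pre_glucose": -0.46,
    "minutes_since_meal": 0.002,
    "nl_minutes": -0.1,
    "postprandial": 1.2,
    "hba1c": 0.24,
    "duration": -0.024,
    "pct_aamhr": 0.0183,
    "sulfonylurea": -0.2,
    "age": -0.004,
    "session_number": -0.06,
    "sex": 0.0,
    "metformin": 0.0,
}


@dataclass
class CohortConfig:
    """Generative parameters for one synthetic cohort.

    Covariate means/SDs and category proportions default to the development
    cohort they emulate (middle-aged, orally medicated T2DM exercisers);
    variance components are calibrated so fixed effects explain roughly
    two-thirds of outcome variance and fixed-plus-subject effects roughly
    three-quarters.
    """

    n_subjects: int = 56
    sessions_per_subject: int | tuple[int, int] = (5, 12)
    seed: int = 0

    # subject-level covariates
    age_mean: float = 54.3
    age_sd: float = 7.9
    hba1c_mean: float = 7.1
    hba1c_sd: float = 1.8
    p_male: float = 0.678
    p_metformin: float = 0.607
    p_sulfonylurea: float = 0.696
    glucose_mean_mean: float = 9.5  # between-subject mean of habitual pre-exercise glucose
    glucose_mean_sd: float = 2.6
    glucose_sd_mean: float = 1.8  # within-subject SD of pre-exercise glucose
    glucose_sd_sd: float = 0.6

    # session-level covariates
    p_postprandial: float = 0.803
    minutes_postprandial_range: tuple[float, float] = (10.0, 120.0)
    minutes_preprandial_range: tuple[float, float] = (121.0, 420.0)
    duration_mean: float = 44.7
    duration_sd: float = 14.6
    pct_aamhr_mean: float = 72.5
    pct_aamhr_sd: float = 3.7

    # outcome model.  The negative intercept-slope correlation keeps the
    # subject-level variance modest at typical glycemia while letting
    # subjects differ genuinely in their sensitivity to pre-exercise
    # glucose (the variance of b0 + b1*pre is smallest near the cohort
    # mean and grows toward the extremes).
    beta: dict = field(default_factory=lambda: dict(DEFAULT_BETA))
    intercept_sd: float = 2.0  # mmol/L, random-intercept SD
    slope_sd: float = 0.25  # random slope on pre-exercise glucose
    intercept_slope_corr: float = -0.9
    residual_sd: float = 1.05  # mmol/L
    measurement_noise: str = "off"  # {"off", "iso_band"}

    def __post_init__(self):
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be non-negative")
        for name in ("age_sd", "hba1c_sd", "glucose_mean_sd", "glucose_sd_sd",
                     "duration_sd", "pct_aamhr_sd", "intercept_sd", "slope_sd",
                     "residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("p_male", "p_metformin", "p_sulfonylurea", "p_postprandial"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not -1.0 <= self.intercept_slope_corr <= 1.0:
            raise ValueError("intercept_slope_corr must be in [-1, 1]")
        if self.measurement_noise not in ("off", "iso_band"):
            raise ValueError("measurement_noise must be 'off' or 'iso_band'")
        if np.linalg.eigvalsh(self.random_cov()).min() < -1e-12:
            raise ValueError("random-effect covariance is not positive semi-definite")

    def random_cov(self) -> np.ndarray:
        """2x2 covariance of (random intercept, random slope)."""
        cov01 = self.intercept_slope_corr * self.intercept_sd * self.slope_sd
        return np.array(
            [[self.intercept_sd**2, cov01], [cov01, self.slope_sd**2]]
        )

    @property
    def t_max(self) -> float:
        return float(self.minutes_preprandial_range[1])

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("sessions_per_subject", "minutes_postprandial_range",
                    "minutes_preprandial_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def prospective_cohort_config(seed: int = 0, **overrides) -> CohortConfig:
    """Configuration emulating the prospectively-collected test cohort.

    Compared to the development defaults: fewer, shorter, slightly more
    intense sessions; mostly pre-prandial exercise; lower glycemia; more
    metformin and less sulfonylurea use; balanced sex.
    """
    params = dict(
        n_subjects=47,
        sessions_per_subject=(5, 13),
        age_mean=55.9, age_sd=9.7,
        hba1c_mean=6.9, hba1c_sd=1.1,
        p_male=0.489, p_metformin=0.936, p_sulfonylurea=0.383,
        glucose_mean_mean=7.8, glucose_mean_sd=2.1,
        glucose_sd_mean=1.6, glucose_sd_sd=0.5,
        p_postprandial=0.36,
        duration_mean=34.9, duration_sd=10.3,
        pct_aamhr_mean=75.5, pct_aamhr_sd=8.7,
        seed=seed,
    )
    params.update(overrides)
    return CohortConfig(**params)


def _truncated_normal(rng, mean, sd, low=-np.inf, high=np.inf, size=None):
    """Draw by rejection from N(mean, sd) truncated to (low, high)."""
    if sd == 0:
        return np.full(size, mean, dtype=float) if size else float(mean)
    out = rng.normal(mean, sd, size=size)
    arr = np.atleast_1d(out)
    bad = (arr <= low) | (arr >= high)
    while bad.any():
        arr[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (arr <= low) | (arr >= high)
    return arr if size is not None else float(arr[0])


def generate_subjects(config: CohortConfig) -> pd.DataFrame:
    """Draw the subject table: demographics, medications, habitual glycemia,
    and per-subject random effects (fixed across that subject's sessions)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    if n == 0:
        return pd.DataFrame(
            columns=["subject_id", "age", "sex", "hba1c", "metformin", "sulfonylurea",
                     "glucose_mean", "glucose_sd", "random_intercept", "random_slope"]
        )
    re = rng.multivariate_normal(np.zeros(2), config.random_cov(), size=n)
    df = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:03d}" for i in range(n)],
            "age": _truncated_normal(rng, config.age_mean, config.age_sd, low=18, high=95, size=n),
            "sex": np.where(rng.random(n) < config.p_male, "male", "female"),
            "hba1c": _truncated_normal(rng, config.hba1c_mean, config.hba1c_sd, low=3.0, size=n),
            "metformin": (rng.random(n) < config.p_metformin).astype(int),
            "sulfonylurea": (rng.random(n) < config.p_sulfonylurea).astype(int),
            "glucose_mean": _truncated_normal(
                rng, config.glucose_mean_mean, config.glucose_mean_sd, low=2.0, size=n
            ),
            "glucose_sd": _truncated_normal(
                rng, config.glucose_sd_mean, config.glucose_sd_sd, low=0.0, size=n
            ),
            "random_intercept": re[:, 0],
            "random_slope": re[:, 1],
        }
    )
    return df


def generate_sessions(subjects: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Draw exercise sessions for each subject (post_glucose left unset).

    Sessions are independent given the subject: meal timing comes from a
    two-component uniform mixture so both prandial states occur, duration and
    %AAMHR from truncated normals, and pre-exercise glucose from the
    subject's habitual mean and within-subject SD (floored at 0.5 mmol/L).
    """
    if len(subjects) == 0:
        raise ValueError("subjects table is empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    lo_k = (
        config.sessions_per_subject
        if isinstance(config.sessions_per_subject, int)
        else None
    )
    rows = []
    for subj in subjects.itertuples(index=False):
        if lo_k is not None:
            k = lo_k
        else:
            lo, hi = config.sessions_per_subject
            k = int(rng.integers(lo, hi + 1))
        if k == 0:
            logger.warning("subject %s configured with zero sessions", subj.subject_id)
            continue
        post_meal = rng.random(k) < config.p_postprandial
        minutes = np.where(
            post_meal,
            rng.uniform(*config.minutes_postprandial_range, size=k),
            rng.uniform(*config.minutes_preprandial_range, size=k),
        )
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": subj.subject_id,
                    "session_number": np.arange(1, k + 1),
                    "pre_glucose": _truncated_normal(
                        rng, subj.glucose_mean, subj.glucose_sd, low=0.5, size=k
                    ),
                    "minutes_since_meal": minutes,
                    "duration": _truncated_normal(
                        rng, config.duration_mean, config.duration_sd, low=5.0, size=k
                    ),
                    "pct_aamhr": _truncated_normal(
                        rng, config.pct_aamhr_mean, config.pct_aamhr_sd, low=30.0, high=100.0, size=k
                    ),
                }
            )
        )
    if not rows:
        logger.warning("no sessions generated")
        return pd.DataFrame(
            columns=["subject_id", "session_number", "pre_glucose",
                     "minutes_since_meal", "duration", "pct_aamhr"]
        )
    return pd.concat(rows, ignore_index=True)


def _design_row_matrix(sessions: pd.DataFrame, subjects: pd.DataFrame,
                       beta: dict, t_max: float) -> np.ndarray:
    """Fixed-effect linear predictor x'beta for every session row."""
    subj = subjects.set_index("subject_id")
    merged = sessions.join(subj, on="subject_id")
    cols = {
        "intercept": np.ones(len(merged)),
        "pre_glucose": merged["pre_glucose"].to_numpy(float),
        "minutes_since_meal": merged["minutes_since_meal"].to_numpy(float),
        "nl_minutes": transform_minutes(merged["minutes_since_meal"].to_numpy(float), t_max),
        "postprandial": postprandial_flag(merged["minutes_since_meal"].to_numpy(float)).astype(float),
        "hba1c": merged["hba1c"].to_numpy(float),
        "duration": merged["duration"].to_numpy(float),
        "pct_aamhr": merged["pct_aamhr"].to_numpy(float),
        "sulfonylurea": merged["sulfonylurea"].to_numpy(float),
        "age": merged["age"].to_numpy(float),
        "session_number": merged["session_number"].to_numpy(float),
        "sex": (merged["sex"] == "male").to_numpy(float),
        "metformin": merged["metformin"].to_numpy(float),
    }
    eta = np.zeros(len(merged))
    for name, coef in beta.items():
        if name not in cols:
            raise KeyError(f"outcome model names unknown covariate {name!r}")
        eta += coef * cols[name]
    return eta


def apply_outcome_model(sessions: pd.DataFrame, subjects: pd.DataFrame,
                        config: CohortConfig) -> pd.DataFrame:
    """Set post_glucose from the mixed-effects generative model.

    delta = x'beta + b0_subject + b1_subject * pre_glucose + Normal(0, residual_sd).
    """
    for col in ("pre_glucose", "minutes_since_meal", "duration", "pct_aamhr"):
        missing = sessions[col].isna()
        if missing.any():
            bad = sessions.loc[missing, ["subject_id", "session_number"]].iloc[0]
            raise ValueError(
                f"missing covariate {col!r} for subject {bad.subject_id} "
                f"session {bad.session_number}"
            )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    eta = _design_row_matrix(sessions, subjects, config.beta, config.t_max)
    subj = subjects.set_index("subject_id")
    b0 = subj["random_intercept"].reindex(sessions["subject_id"]).to_numpy(float)
    b1 = subj["random_slope"].reindex(sessions["subject_id"]).to_numpy(float)
    eps = rng.normal(0.0, config.residual_sd, size=len(sessions))
    delta = eta + b0 + b1 * sessions["pre_glucose"].to_numpy(float) + eps
    out = sessions.copy()
    # physiological floor: measured glucose cannot reach zero
    out["post_glucose"] = np.maximum(out["pre_glucose"] + delta, 0.3)
    return out


def iso_error_band(true_glucose: np.ndarray) -> np.ndarray:
    """Half-width of the self-monitoring meter accuracy band, mmol/L."""
    g = np.asarray(true_glucose, dtype=float)
    return np.where(g < 4.2, 0.83, 0.20 * g)


def add_measurement_noise(sessions: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Perturb pre/post glucose with meter error when enabled.

    Noise is uniform on the accuracy band of the true value (±0.83 mmol/L
    below 4.2 mmol/L, ±20% otherwise), independently for the pre- and
    post-exercise measurements.  Identity when the switch is off.
    """
    if config.measurement_noise == "off":
        return sessions
    if sessions["post_glucose"].isna().any():
        raise ValueError("post_glucose must be set before adding measurement noise")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    out = sessions.copy()
    for col in ("pre_glucose", "post_glucose"):
        truth = out[col].to_numpy(float)
        band = iso_error_band(truth)
        out[col] = truth + rng.uniform(-band, band)
    return out


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full pipeline: subjects, sessions, outcomes, optional meter noise.

    Returns ``(subjects, sessions)``; sessions carry all canonical CSV
    columns.  Identical config (including seed) gives identical output.
    """
    subjects = generate_subjects(config)
    sessions = generate_sessions(subjects, config)
    sessions = apply_outcome_model(sessions, subjects, config)
    sessions = add_measurement_noise(sessions, config)
    return subjects, sessions


def sessions_to_csv(sessions: pd.DataFrame, subjects: pd.DataFrame, path) -> None:
    """Write the canonical per-session CSV (UTF-8, header, '.' decimals)."""
    subj = subjects.set_index("subject_id")[["age", "sex", "hba1c", "metformin", "sulfonylurea"]]
    full = sessions.join(subj, on="subject_id")
    full[SESSION_CSV_COLUMNS].to_csv(path, index=False, encoding="utf-8")


def read_session_csv(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the canonical session CSV; returns (subjects, sessions) tables.

    Schema is strict: all canonical columns must be present, glucose in
    mmol/L and times in minutes.
    """
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in SESSION_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"session CSV lacks column(s): {missing}")
    if (df["pre_glucose"] > 40).any():
        raise ValueError("pre_glucose above 40 mmol/L: values look like mg/dL, expected mmol/L")
    subjects = (
        df[["subject_id", "age", "sex", "hba1c", "metformin", "sulfonylurea"]]
        .drop_duplicates("subject_id")
        .reset_index(drop=True)
    )
    sessions = df[
        ["subject_id", "session_number", "pre_glucose", "post_glucose",
         "minutes_since_meal", "duration", "pct_aamhr"]
    ].copy()
    return subjects, sessions
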