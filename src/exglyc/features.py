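"""Derived predictors for the glucose-response model.

Candidate predictors for the change in blood glucose with an exercise bout
(``delta_glucose = post_glucose - pre_glucose``, mmol/L):

* ``pre_glucose`` — pre-exercise blood glucose, mmol/L
* ``minutes_since_meal`` — linear minutes since the last meal
* ``nl_minutes`` — a non-linear transform of minutes since eating that rises
  and falls like postprandial insulin over the first three hours and then
  decreases linearly (counter-regulatory hormone dominance) down to -1 at the
  longest observed fast
* ``postprandial`` — 1 if exercise began within 120 minutes of eating
* ``hba1c`` — glycated hemoglobin, percent
* ``duration`` — exercise duration, minutes
* ``pct_aamhr`` — mean exercise heart rate as a percentage of the
  age-adjusted maximum heart rate (220 - age)
* ``sulfonylurea``, ``metformin`` — oral-medication status dummies
* ``age`` — years; ``sex`` — male=1 dummy; ``session_number`` — exercise
  session index within subject
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: All candidate predictors, in canonical order.
CANDIDATE_PREDICTORS = (
    "pre_glucose",
    "minutes_since_meal",
    "nl_minutes",
    "postprandial",
    "hba1c",
    "duration",
    "pct_aamhr",
    "sulfonylurea",
    "age",
    "session_number",
    "sex",
    "metformin",
)

#: Columns that come from the subject table rather than the session table.
SUBJECT_COLUMNS = ("age", "sex", "hba1c", "metformin", "sulfonylurea")

#: Predictors that vary within a subject across sessions (random-slope
#: candidates); the rest vary only between subjects (grouping-factor
#: candidates).
WITHIN_SUBJECT_PREDICTORS = frozenset(
    {
        "pre_glucose",
        "minutes_since_meal",
        "nl_minutes",
        "postprandial",
        "duration",
        "pct_aamhr",
        "session_number",
    }
)

POSTPRANDIAL_CUTOFF_MIN = 120.0
INSULIN_PHASE_END_MIN = 180.0


def transform_minutes(t, t_max: float, clip: bool = False):
    """Non-linear transform of minutes since eating, in [-1, 1].

    For ``t <= 180`` the value is ``sin(pi * t / 180)`` — a half-sine hump
    peaking at 1 at t=90 min, mimicking the postprandial insulin excursion.
    For ``t > 180`` the value decreases linearly from 0 to -1 at ``t_max``,
    reflecting rising counter-regulatory hormone influence with longer
    fasts.  The two branches join continuously at t=180 (both zero).

    Parameters
    ----------
    t : float or array-like
        Minutes since the last meal, >= 0.
    t_max : float
        Largest minutes-since-meal value in the data in scope; must exceed
        180 so the fasting branch has positive length.
    clip : bool
        When predicting new sessions with a transform anchored on a
        training set, values beyond ``t_max`` are capped at the -1 floor
        instead of raising.
    """
    if t_max <= INSULIN_PHASE_END_MIN:
        raise ValueError(f"t_max must exceed {INSULIN_PHASE_END_MIN:g} min, got {t_max!r}")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("minutes since meal must be non-negative")
    if np.any(t_arr > t_max):
        if not clip:
            raise ValueError(
                f"minutes since meal exceeds t_max={t_max:g}; recompute t_max from the data in scope"
            )
        t_arr = np.minimum(t_arr, t_max)
    hump = np.sin(np.pi * t_arr / INSULIN_PHASE_END_MIN)
    fast = -(t_arr - INSULIN_PHASE_END_MIN) / (t_max - INSULIN_PHASE_END_MIN)
    out = np.where(t_arr <= INSULIN_PHASE_END_MIN, hump, fast)
    return float(out) if np.isscalar(t) or out.ndim == 0 else out


def postprandial_flag(t):
    """1 if exercise began within 120 minutes of eating, else 0."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("minutes since meal must be non-negative")
    out = (t_arr <= POSTPRANDIAL_CUTOFF_MIN).astype(int)
    return int(out) if np.isscalar(t) or out.ndim == 0 else out


def pct_aamhr(mean_hr, age):
    """Mean heart rate as percent of the age-adjusted maximum (220 - age)."""
    hr = np.asarray(mean_hr, dtype=float)
    age_arr = np.asarray(age, dtype=float)
    if np.any(hr <= 0):
        raise ValueError("mean heart rate must be positive")
    if np.any(age_arr <= 0) or np.any(age_arr >= 120):
        raise ValueError("age must be in (0, 120) years")
    out = 100.0 * hr / (220.0 - age_arr)
    return float(out) if np.isscalar(mean_hr) and np.isscalar(age) else out


@dataclass
class DesignMatrix:
    """Design matrix for one model fit, aligned row-for-row to sessions.

    ``X`` holds the named predictor columns (no intercept column; model code
    adds one), ``y`` the glucose change in mmol/L, ``groups`` the subject
    identifier, and ``session_number`` the within-subject session index used
    by the validation protocols.
    """

    X: pd.DataFrame
    y: pd.Series
    groups: pd.Series
    session_number: pd.Series
    t_max: float
    n_dropped: int = 0
    extra: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, mask) -> "DesignMatrix":
        """Row-subset by boolean mask or positional index, keeping alignment."""
        idx = np.asarray(mask)
        take = (lambda obj: obj.loc[idx] if idx.dtype == bool else obj.iloc[idx])
        return DesignMatrix(
            X=take(self.X),
            y=take(self.y),
            groups=take(self.groups),
            session_number=take(self.session_number),
            t_max=self.t_max,
            n_dropped=0,
            extra=take(self.extra) if len(self.extra) else self.extra,
        )

    def to_frame(self) -> pd.DataFrame:
        out = self.X.copy()
        out.insert(0, "subject_id", self.groups)
        out["delta_glucose"] = self.y
        return out


def merge_sessions_subjects(sessions: pd.DataFrame, subjects: pd.DataFrame) -> pd.DataFrame:
    """Join the session table to subject-level covariates on subject_id."""
    subj_cols = ["subject_id"] + [c for c in SUBJECT_COLUMNS if c in subjects.columns]
    overlap = [c for c in subj_cols[1:] if c in sessions.columns]
    merged = sessions.drop(columns=overlap).merge(
        subjects[subj_cols], on="subject_id", how="left", validate="many_to_one"
    )
    return merged


def build_design(
    sessions: pd.DataFrame,
    subjects: pd.DataFrame | None = None,
    predictor_set=CANDIDATE_PREDICTORS,
    t_max: float | None = None,
) -> DesignMatrix:
    """Assemble the design matrix for a set of sessions.

    Derived columns (``nl_minutes``, ``postprandial``, ``pct_aamhr``) are
    computed on the fly when absent.  ``t_max`` for the minutes transform is
    recomputed from the sessions in scope unless supplied (a validation
    protocol passes the training-set value when predicting new rows).  Rows
    missing any requested predictor or the outcome are dropped complete-case,
    with the drop count logged and recorded on the result.
    """
    predictor_set = list(predictor_set)
    unknown = [p for p in predictor_set if p not in CANDIDATE_PREDICTORS]
    if unknown:
        raise ValueError(
            f"unknown predictor(s) {unknown}; valid names: {list(CANDIDATE_PREDICTORS)}"
        )
    df = (
        merge_sessions_subjects(sessions, subjects)
        if subjects is not None
        else sessions.copy()
    )

    if "delta_glucose" not in df.columns:
        df["delta_glucose"] = df["post_glucose"] - df["pre_glucose"]
    if "sex" in df.columns and df["sex"].dtype == object:
        df["sex"] = (df["sex"] == "male").astype(int)

    external_tmax = t_max is not None
    if t_max is None:
        t_max = float(df["minutes_since_meal"].max())
        if t_max <= INSULIN_PHASE_END_MIN:
            # no observed fast beyond the insulin phase: fall back to a
            # typical longest-fast anchor so the transform stays defined
            t_max = 420.0
    if "nl_minutes" in predictor_set and "nl_minutes" not in df.columns:
        df["nl_minutes"] = transform_minutes(
            df["minutes_since_meal"].to_numpy(), t_max, clip=external_tmax
        )
    if "postprandial" in predictor_set and "postprandial" not in df.columns:
        df["postprandial"] = postprandial_flag(df["minutes_since_meal"].to_numpy())
    if "pct_aamhr" in predictor_set and "pct_aamhr" not in df.columns:
        df["pct_aamhr"] = pct_aamhr(df["mean_hr"].to_numpy(), df["age"].to_numpy())

    needed = predictor_set + ["delta_glucose", "subject_id", "session_number"]
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise ValueError(f"session table lacks required column(s): {missing_cols}")
    complete = df[needed].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("build_design: dropped %d incomplete row(s)", n_dropped)
    df = df.loc[complete].reset_index(drop=True)

    return DesignMatrix(
        X=df[predictor_set].astype(float),
        y=df["delta_glucose"].astype(float),
        groups=df["subject_id"],
        session_number=df["session_number"].astype(int),
        t_max=t_max,
        n_dropped=n_dropped,
        extra=df[
            [c for c in ("pre_glucose", "post_glucose", "minutes_since_meal") if c in df.columns]
        ],
    )
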