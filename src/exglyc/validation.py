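"""Model validation against glucometer measurement error.

A prediction counts as accurate when the predicted glucose change is within
the self-monitoring meter's regulatory accuracy band of the actual change:
±0.83 mmol/L when the measured post-exercise glucose is below 4.2 mmol/L,
±20% of the measured value otherwise.  Two protocols are provided:

* leave-one-session-out cross-validation on a development dataset, and
* a prospective per-subject/per-session protocol for a test dataset, where
  each session is predicted from a model refit on that subject's strictly
  earlier sessions plus all sessions of every other subject (no future
  information from the target subject ever enters the training set).

Practical utility is summarized as the number of subjects with at most one
model error after their third exercise session, and per-subject absolute
error distributions for box-plot style displays.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import DesignMatrix, build_design
from .lmm import RandomSpec, fit_lmm, predict

logger = logging.getLogger(__name__)

HYPO_BAND_MMOL = 0.83
HYPO_CUTOFF_MMOL = 4.2
RELATIVE_BAND = 0.20


@dataclass(frozen=True)
class ModelSpec:
    """The prediction model: fixed-effect predictors and random structure."""

    predictors: tuple[str, ...]
    random_spec: RandomSpec = RandomSpec(slope_terms=("pre_glucose",))


@dataclass
class AccuracyReport:
    overall_accuracy: float          # percent of predictions within error
    accuracy_postprandial: float     # percent, sessions <= 120 min since meal
    accuracy_preprandial: float      # percent, sessions > 120 min
    n_predictions: int
    n_postprandial: int
    n_preprandial: int
    utility_count: int               # subjects with <= 1 error after session 3
    n_subjects: int
    per_subject: pd.DataFrame
    records: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)

    def to_json(self, path=None) -> str:
        payload = {
            k: getattr(self, k)
            for k in (
                "overall_accuracy", "accuracy_postprandial", "accuracy_preprandial",
                "n_predictions", "n_postprandial", "n_preprandial",
                "utility_count", "n_subjects",
            )
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def error_threshold(measured_glucose) -> float | np.ndarray:
    """Half-width (mmol/L) of the meter accuracy band at a measured value."""
    g = np.asarray(measured_glucose, dtype=float)
    if np.any(g <= 0):
        raise ValueError("measured glucose must be positive")
    out = np.where(g < HYPO_CUTOFF_MMOL, HYPO_BAND_MMOL, RELATIVE_BAND * g)
    return float(out) if np.isscalar(measured_glucose) or out.ndim == 0 else out


def judge_prediction(predicted_delta, actual_delta, actual_post):
    """Classify one prediction against the measurement-error band.

    Returns ``(threshold, within_error)``; a tie at the band edge counts as
    within error.
    """
    thr = error_threshold(actual_post)
    err = np.abs(np.asarray(predicted_delta) - np.asarray(actual_delta))
    # band edge inclusive, robust to float representation of the tie
    within = err <= thr * (1.0 + 1e-12) + 1e-12
    if np.ndim(within) == 0:
        return float(thr), bool(within)
    return thr, within


def _records_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    df["abs_error"] = (df["predicted_delta"] - df["actual_delta"]).abs()
    return df


def _summarize(records: pd.DataFrame) -> AccuracyReport:
    post = records[records["postprandial"] == 1]
    pre = records[records["postprandial"] == 0]

    def pct(df):
        return 100.0 * df["within_error"].mean() if len(df) else float("nan")

    return AccuracyReport(
        overall_accuracy=pct(records),
        accuracy_postprandial=pct(post),
        accuracy_preprandial=pct(pre),
        n_predictions=len(records),
        n_postprandial=len(post),
        n_preprandial=len(pre),
        utility_count=utility_metric(records),
        n_subjects=records["subject_id"].nunique(),
        per_subject=per_subject_summary(records),
        records=records,
    )


def _fit_and_predict(train: DesignMatrix, test_rows: pd.DataFrame,
                     spec: ModelSpec, init=None) -> np.ndarray:
    fit = fit_lmm(train, spec.random_spec, init=init)
    return predict(fit, test_rows, use_random=True)


def loocv(sessions: pd.DataFrame, subjects: pd.DataFrame,
          spec: ModelSpec) -> AccuracyReport:
    """Leave-one-session-out cross-validation on a development dataset.

    Each session is predicted by a model refit on every other session; the
    held-out subject's remaining sessions supply its random-effect
    estimates (a subject with a single session gets the population
    prediction, logged).
    """
    design = build_design(sessions, subjects, list(spec.predictors))
    n = len(design)
    if n < 2:
        raise ValueError("need at least 2 sessions for cross-validation")
    frame = design.X.copy()
    frame["subject_id"] = design.groups.values
    rows = []
    counts = design.groups.value_counts()
    full_fit = fit_lmm(design, spec.random_spec)  # warm start for the refits
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        train = design.subset(mask)
        sid = design.groups.iloc[i]
        if counts[sid] == 1:
            logger.info("subject %s has a single session: population prediction", sid)
        pred = _fit_and_predict(train, frame.iloc[[i]], spec, init=full_fit)[0]
        actual = float(design.y.iloc[i])
        post_g = float(design.extra["post_glucose"].iloc[i])
        thr, within = judge_prediction(pred, actual, post_g)
        rows.append(
            dict(
                subject_id=sid,
                session_number=int(design.session_number.iloc[i]),
                predicted_delta=pred,
                actual_delta=actual,
                actual_post=post_g,
                threshold=thr,
                within_error=within,
                actual_pre=float(design.extra["pre_glucose"].iloc[i]),
                postprandial=int(design.X["postprandial"].iloc[i])
                if "postprandial" in design.X
                else int(design.extra["minutes_since_meal"].iloc[i] <= 120),
                n_prior_sessions=int(counts[sid]) - 1,
            )
        )
    return _summarize(_records_frame(rows))


def prospective_validate(sessions: pd.DataFrame, subjects: pd.DataFrame,
                         spec: ModelSpec) -> AccuracyReport:
    """Prospective per-subject/per-session validation of a test dataset.

    For each subject x session, the model is refit on the union of that
    subject's strictly earlier sessions and all sessions of all other
    subjects, then predicts the session of interest.  The transform anchor
    t_max for the non-linear minutes predictor is recomputed from each
    training set.  First sessions are predicted with population effects
    only.
    """
    if sessions["subject_id"].nunique() < 2:
        raise ValueError("prospective validation needs at least 2 subjects")
    rows = []
    order = sessions.sort_values(["subject_id", "session_number"])
    for sid, sub in order.groupby("subject_id", sort=False):
        # warm start each refit from the same subject's previous-session fit:
        # that fit depends only on strictly-earlier data, so the no-leakage
        # guarantee (future sessions never influence a prediction) holds
        # bit-for-bit
        prev_fit = None
        for _, sess_row in sub.iterrows():
            k = sess_row["session_number"]
            train_mask = (sessions["subject_id"] != sid) | (
                sessions["session_number"] < k
            )
            train_sessions = sessions[train_mask]
            train = build_design(train_sessions, subjects, list(spec.predictors))
            test = build_design(
                sessions[(sessions["subject_id"] == sid)
                         & (sessions["session_number"] == k)],
                subjects, list(spec.predictors), t_max=train.t_max,
            )
            if len(test) == 0:
                continue  # incomplete row, dropped like the training rows
            frame = test.X.copy()
            frame["subject_id"] = test.groups.values
            fit = fit_lmm(train, spec.random_spec, init=prev_fit)
            prev_fit = fit
            pred = float(predict(fit, frame, use_random=True)[0])
            actual = float(test.y.iloc[0])
            post_g = float(test.extra["post_glucose"].iloc[0])
            thr, within = judge_prediction(pred, actual, post_g)
            n_prior = int(((sessions["subject_id"] == sid)
                           & (sessions["session_number"] < k)).sum())
            rows.append(
                dict(
                    subject_id=sid,
                    session_number=int(k),
                    predicted_delta=pred,
                    actual_delta=actual,
                    actual_post=post_g,
                    threshold=thr,
                    within_error=within,
                    actual_pre=float(test.extra["pre_glucose"].iloc[0]),
                    postprandial=int(test.X["postprandial"].iloc[0])
                    if "postprandial" in test.X
                    else int(test.extra["minutes_since_meal"].iloc[0] <= 120),
                    n_prior_sessions=n_prior,
                )
            )
    return _summarize(_records_frame(rows))


def utility_metric(records: pd.DataFrame) -> int:
    """Subjects with at most one model error after the third session.

    Subjects with no sessions beyond the third satisfy the criterion
    vacuously (they are logged).
    """
    count = 0
    for sid, sub in records.groupby("subject_id"):
        late = sub[sub["session_number"] > 3]
        if len(late) == 0:
            logger.info("subject %s has no sessions beyond the 3rd (counted)", sid)
        if (~late["within_error"]).sum() <= 1:
            count += 1
    return count


def per_subject_summary(records: pd.DataFrame,
                        sort_by: str = "median_abs_error") -> pd.DataFrame:
    """Box-plot style summary of absolute model error per subject.

    Median, quartiles (midpoint interpolation), and 1.5 IQR whisker bounds,
    sorted ascending by median absolute error (ties broken by subject id).
    ``sort_by="sd_pre_glucose"`` orders instead by the within-subject SD of
    pre-exercise glucose when the records carry a ``pre_glucose`` column.
    """
    rows = []
    for sid, sub in records.groupby("subject_id"):
        err = sub["abs_error"] if "abs_error" in sub else (
            (sub["predicted_delta"] - sub["actual_delta"]).abs()
        )
        q1, med, q3 = np.percentile(err, [25, 50, 75], method="midpoint")
        iqr = q3 - q1
        row = dict(
            subject_id=sid,
            n=len(sub),
            median_abs_error=med,
            q1=q1,
            q3=q3,
            whisker_low=q1 - 1.5 * iqr,
            whisker_high=q3 + 1.5 * iqr,
            n_errors=int((~sub["within_error"]).sum()),
        )
        if "actual_pre" in sub:
            row["sd_pre_glucose"] = float(sub["actual_pre"].std())
        rows.append(row)
    out = pd.DataFrame(rows)
    key = sort_by if sort_by in out.columns else "median_abs_error"
    return out.sort_values([key, "subject_id"], kind="mergesort").reset_index(drop=True)
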