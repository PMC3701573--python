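"""End-to-end development and test workflows.

``run_development`` mirrors the model-building sequence on a development
dataset: build the twelve candidate predictors, select among them with the
mixed-effects LASSO (BIC-minimized path, forced predictors unpenalized),
estimate LMG relative importance with bootstrap intervals on first-session
rows, test random-effect structures sequentially in importance order
against the random-intercepts baseline, and cross-validate accuracy
leave-one-session-out.

``run_test`` evaluates the developed model specification (predictors +
random structure, not coefficients) on an independent test dataset with the
prospective per-subject/per-session protocol, reports accuracy overall and
by prandial state, variance explained (marginal and conditional, from an
intercepts-only refit), the practical-utility count, per-subject error
summaries, and the post-hoc mixed-effects logistic model of prediction
error.

Every artifact is written as CSV/JSON stamped with a hash of the
configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import (
    CANDIDATE_PREDICTORS,
    WITHIN_SUBJECT_PREDICTORS,
    build_design,
)
from .lmm import RandomSpec, fit_lmm, likelihood_ratio_test, r2_nakagawa
from .lasso import LassoConfig, LassoPath, run_path_and_select, path_to_csv
from .importance import ImportanceResult, bootstrap_ci, first_sessions
from .validation import AccuracyReport, ModelSpec, loocv, prospective_validate
from .error_model import ErrorModelFit, fit_logistic_glmm, rolling_sd_features

logger = logging.getLogger(__name__)

ALPHA_STRUCTURE = 0.05


@dataclass
class RunConfig:
    """Workflow configuration: model-search settings, stage toggles, seeds."""

    candidate_predictors: tuple[str, ...] = CANDIDATE_PREDICTORS
    forced: tuple[str, ...] = ("pre_glucose", "pct_aamhr", "duration")
    lasso_step: float = 0.1
    n_boot: int = 1000
    seed: int = 0
    run_selection: bool = True
    run_importance: bool = True
    run_structure: bool = True
    run_loocv: bool = True
    run_error_model: bool = True

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("candidate_predictors", "forced"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class DevelopmentReport:
    lasso_path: LassoPath
    selected_predictors: tuple[str, ...]
    coefficients: pd.Series           # relaxed refit on the selected support
    importance: ImportanceResult | None
    structure_tests: pd.DataFrame
    model_spec: ModelSpec
    loocv_report: AccuracyReport | None
    config_hash: str


@dataclass
class TestReport:
    accuracy: AccuracyReport
    r2_marginal: float
    r2_conditional: float
    error_model: ErrorModelFit | None
    model_spec: ModelSpec
    config_hash: str


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.time()


def _stage_done(name: str, t0: float):
    logger.info("stage %s done in %.1fs", name, time.time() - t0)


def structure_tests(design, order: list[str]) -> tuple[pd.DataFrame, RandomSpec]:
    """Sequential LR tests of random-effect structure, importance-ordered.

    Each candidate predictor is tested against the common random-intercepts
    baseline: within-subject predictors as a random slope, between-subject
    predictors as an extra random-intercept grouping over their observed
    levels.  The returned RandomSpec carries the significant slope terms
    (extra groupings are reported but not accumulated into the prediction
    model, whose R-squared decomposition needs a single grouping level).
    """
    baseline = fit_lmm(design)
    rows = []
    slopes: list[str] = []
    for name in order:
        if name not in design.columns:
            continue
        if name in WITHIN_SUBJECT_PREDICTORS:
            spec = RandomSpec(slope_terms=(name,))
            kind = "random slope"
        else:
            spec = RandomSpec(extra_grouping=name)
            kind = "grouping-factor intercept"
        try:
            alt = fit_lmm(design, spec)
            lr, df, p = likelihood_ratio_test(baseline, alt)
        except Exception as exc:  # rank issues on degenerate designs
            logger.warning("structure test for %s failed: %s", name, exc)
            rows.append(dict(variable=name, structure=kind, lr=np.nan, df=np.nan,
                             p_value=np.nan, significant=False))
            continue
        sig = p < ALPHA_STRUCTURE
        if sig and kind == "random slope":
            slopes.append(name)
        rows.append(dict(variable=name, structure=kind, lr=lr, df=df,
                         p_value=p, significant=sig))
    spec = RandomSpec(slope_terms=tuple(slopes))
    return pd.DataFrame(rows), spec


def run_development(sessions: pd.DataFrame, subjects: pd.DataFrame,
                    config: RunConfig = RunConfig(),
                    out_dir=None) -> DevelopmentReport:
    """Full development workflow on one dataset; optionally writes artifacts."""
    chash = config.hash()
    design = build_design(sessions, subjects, list(config.candidate_predictors))

    t0 = _stage("selection")
    lasso_cfg = LassoConfig(forced=config.forced, step=config.lasso_step)
    path = run_path_and_select(design, RandomSpec(), lasso_cfg)
    selected = tuple(
        c for c in config.candidate_predictors
        if c in config.forced or c in path.selected_support
    )
    _stage_done("selection", t0)

    importance = None
    order = [c for c in selected]
    if config.run_importance:
        t0 = _stage("importance")
        first = first_sessions(build_design(sessions, subjects, list(selected)))
        importance = bootstrap_ci(
            first, n_boot=config.n_boot, seed=config.seed
        )
        ranked = importance.shares.sort_values(ascending=False).index.tolist()
        order = ranked + [c for c in selected if c not in ranked]
        _stage_done("importance", t0)

    sel_design = build_design(sessions, subjects, list(selected))
    if config.run_structure:
        t0 = _stage("structure")
        tests, random_spec = structure_tests(sel_design, order)
        _stage_done("structure", t0)
    else:
        tests = pd.DataFrame()
        random_spec = RandomSpec(slope_terms=("pre_glucose",))
    model_spec = ModelSpec(predictors=selected, random_spec=random_spec)

    loocv_report = None
    if config.run_loocv:
        t0 = _stage("loocv")
        loocv_report = loocv(sessions, subjects, model_spec)
        _stage_done("loocv", t0)

    report = DevelopmentReport(
        lasso_path=path,
        selected_predictors=selected,
        coefficients=path.selected_fit.beta,
        importance=importance,
        structure_tests=tests,
        model_spec=model_spec,
        loocv_report=loocv_report,
        config_hash=chash,
    )
    if out_dir is not None:
        _write_development(report, config, Path(out_dir))
    return report


def run_test(sessions: pd.DataFrame, subjects: pd.DataFrame,
             model_spec: ModelSpec, config: RunConfig = RunConfig(),
             out_dir=None) -> TestReport:
    """Prospective evaluation of a developed model spec on a test dataset."""
    chash = config.hash()
    t0 = _stage("prospective validation")
    accuracy = prospective_validate(sessions, subjects, model_spec)
    _stage_done("prospective validation", t0)

    # variance explained: intercepts-only refit on the full test design
    design = build_design(sessions, subjects, list(model_spec.predictors))
    r2m, r2c = r2_nakagawa(fit_lmm(design, RandomSpec()))

    err_fit = None
    if config.run_error_model:
        t0 = _stage("error model")
        feats = rolling_sd_features(sessions)
        key = ["subject_id", "session_number"]
        records = accuracy.records.merge(feats[key + ["sd_pre", "sd_post"]], on=key)
        subj_cols = subjects[["subject_id", "sex", "metformin"]]
        records = records.merge(subj_cols, on="subject_id")
        try:
            err_fit = fit_logistic_glmm(records)
        except ValueError as exc:
            logger.warning("error model not fit: %s", exc)
        _stage_done("error model", t0)

    report = TestReport(
        accuracy=accuracy,
        r2_marginal=r2m,
        r2_conditional=r2c,
        error_model=err_fit,
        model_spec=model_spec,
        config_hash=chash,
    )
    if out_dir is not None:
        _write_test(report, config, Path(out_dir))
    return report


def _stamp(df: pd.DataFrame, chash: str) -> pd.DataFrame:
    out = df.copy()
    out["config_hash"] = chash
    return out


def _write_development(report: DevelopmentReport, config: RunConfig, out: Path):
    out.mkdir(parents=True, exist_ok=True)
    chash = report.config_hash
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump({**dataclasses.asdict(config), "config_hash": chash}, fh)
    with open(out / "lasso_path.csv", "w") as fh:
        path_to_csv(report.lasso_path, fh)
    coef = report.coefficients.rename("coefficient").to_frame()
    if report.importance is not None:
        coef = coef.join(report.importance.to_frame(), how="left")
    _stamp(coef.reset_index(names="variable"), chash).to_csv(
        out / "selected_model.csv", index=False
    )
    _stamp(report.structure_tests, chash).to_csv(
        out / "structure_tests.csv", index=False
    )
    if report.loocv_report is not None:
        report.loocv_report.to_json(out / "loocv_report.json")
        _stamp(report.loocv_report.records, chash).to_csv(
            out / "loocv_records.csv", index=False
        )
    logger.info("development artifacts written to %s", out)


def _write_test(report: TestReport, config: RunConfig, out: Path):
    out.mkdir(parents=True, exist_ok=True)
    chash = report.config_hash
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump({**dataclasses.asdict(config), "config_hash": chash}, fh)
    acc = report.accuracy
    payload = json.loads(acc.to_json())
    payload.update(
        r2_marginal=report.r2_marginal,
        r2_conditional=report.r2_conditional,
        config_hash=chash,
        model_predictors=list(report.model_spec.predictors),
        random_slopes=list(report.model_spec.random_spec.slope_terms),
    )
    with open(out / "test_report.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    _stamp(acc.records, chash).to_csv(out / "prediction_records.csv", index=False)
    # predicted-vs-actual table by prandial state (scatter-plot source)
    _stamp(
        acc.records[
            ["subject_id", "session_number", "predicted_delta", "actual_delta",
             "postprandial", "within_error"]
        ],
        chash,
    ).to_csv(out / "predicted_vs_actual.csv", index=False)
    _stamp(acc.per_subject, chash).to_csv(out / "per_subject_error.csv", index=False)
    if report.error_model is not None:
        report.error_model.to_json(out / "error_model.json")
        _stamp(
            report.error_model.to_frame().reset_index(names="term"), chash
        ).to_csv(out / "error_model.csv", index=False)
    logger.info("test artifacts written to %s", out)
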