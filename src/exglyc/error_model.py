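"""Post-hoc mixed-effects logistic regression of model error.

Asks which subject attributes predict when the glucose model errs: sex,
metformin status, and rolling within-subject variability of pre- and
post-exercise glucose (the SD over the sessions before the one being
predicted).  The outcome is a model error (prediction outside the meter
accuracy band); a random intercept per subject absorbs residual
between-subject differences in error propensity.

The marginal likelihood integrates the random intercept out by adaptive
Gauss-Hermite quadrature (15 nodes by default): per subject the integrand
is re-centered at its posterior mode with a Laplace-matched scale, which
keeps the quadrature accurate even with few sessions per subject.
Continuous covariates are mean-centered and SD-scaled before fitting, so a
reported odds ratio is per 1-SD change for an otherwise average individual;
intervals are Wald on the log-odds scale.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, roots_hermite

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("sex", "metformin", "sd_pre", "sd_post")
GH_NODES = 15
SEPARATION_BOUND = 15.0  # |log-OR| on the standardized scale


@dataclass
class ErrorModelFit:
    odds_ratios: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    coef: pd.Series                  # log-odds scale, standardized covariates
    se: pd.Series
    random_intercept_variance: float
    loglik: float
    n_obs: int
    n_subjects: int
    converged: bool
    scaling: pd.DataFrame            # centering/scaling applied per covariate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"odds_ratio": self.odds_ratios, "ci_low": self.ci_low,
             "ci_high": self.ci_high}
        )

    def to_json(self, path=None) -> str:
        payload = {
            "odds_ratios": self.odds_ratios.to_dict(),
            "ci_low": self.ci_low.to_dict(),
            "ci_high": self.ci_high.to_dict(),
            "random_intercept_variance": self.random_intercept_variance,
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
            "converged": self.converged,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def rolling_sd_features(sessions: pd.DataFrame) -> pd.DataFrame:
    """Within-subject SD of pre/post glucose over strictly earlier sessions.

    For each session, ``sd_pre`` and ``sd_post`` are the sample SDs (n-1
    denominator) of that subject's pre- and post-exercise glucose across
    sessions with a smaller session number.  Sessions with fewer than two
    prior sessions get NaN (and are excluded from the error model).
    """
    out = sessions.sort_values(["subject_id", "session_number"]).copy()
    for col, name in (("pre_glucose", "sd_pre"), ("post_glucose", "sd_post")):
        shifted = (
            out.groupby("subject_id", sort=False)[col]
            .apply(lambda s: s.expanding().std().shift(1))
            .reset_index(level=0, drop=True)
        )
        out[name] = shifted
        out.loc[
            out.groupby("subject_id", sort=False).cumcount() < 2, name
        ] = np.nan
    return out


def _agq_loglik(params, X, y, subj_idx, n_subjects, nodes, weights):
    """Negative marginal log-likelihood by adaptive Gauss-Hermite.

    Per subject, the random intercept is integrated out on nodes shifted to
    the posterior mode (found by Newton; the log-joint is strictly concave)
    and scaled by the Laplace curvature, all subjects vectorized.
    """
    beta = params[:-1]
    log_tau = params[-1]
    tau2 = np.exp(2.0 * log_tau)
    eta0 = X @ beta

    u = np.zeros(n_subjects)
    for _ in range(100):
        p = expit(eta0 + u[subj_idx])
        g = np.bincount(subj_idx, weights=p - y, minlength=n_subjects) + u / tau2
        h = np.bincount(subj_idx, weights=p * (1 - p), minlength=n_subjects) + 1.0 / tau2
        u -= g / h
        if np.max(np.abs(g)) < 1e-12:
            break
    p = expit(eta0 + u[subj_idx])
    h = np.bincount(subj_idx, weights=p * (1 - p), minlength=n_subjects) + 1.0 / tau2
    scale = 1.0 / np.sqrt(h)

    Uk = u[:, None] + np.sqrt(2.0) * scale[:, None] * nodes[None, :]
    logjoint = np.empty((n_subjects, len(nodes)))
    for k in range(len(nodes)):
        lin = eta0 + Uk[subj_idx, k]
        ll = y * lin - np.logaddexp(0.0, lin)
        logjoint[:, k] = np.bincount(subj_idx, weights=ll, minlength=n_subjects)
    logjoint += -0.5 * Uk**2 / tau2 - log_tau - 0.5 * np.log(2.0 * np.pi)
    log_terms = np.log(weights)[None, :] + logjoint + nodes[None, :] ** 2
    m = log_terms.max(axis=1)
    log_int = (
        m
        + np.log(np.sum(np.exp(log_terms - m[:, None]), axis=1))
        + np.log(np.sqrt(2.0) * scale)
    )
    return -float(np.sum(log_int))


def fit_logistic_glmm(records: pd.DataFrame, covariates=DEFAULT_COVARIATES,
                      n_nodes: int = GH_NODES,
                      fixed_tau: float | None = None) -> ErrorModelFit:
    """Fit the random-intercept logistic model of model error.

    ``records`` needs one row per prediction with columns ``subject_id``,
    ``within_error`` (bool), and the covariates (rows with missing
    covariates — e.g. undefined rolling SDs — are dropped).  ``fixed_tau``
    pins the random-intercept SD instead of estimating it (degenerate
    designs with no between-subject heterogeneity).
    """
    covariates = list(covariates)
    df = records.dropna(subset=covariates).copy()
    if df["subject_id"].nunique() < 2:
        raise ValueError("need at least 2 subjects with complete covariates")
    y = (~df["within_error"].astype(bool)).to_numpy(float)  # 1 = model error
    if df["sex"].dtype == object:
        df["sex"] = (df["sex"] == "male").astype(float)

    X_raw = df[covariates].to_numpy(float)
    center = X_raw.mean(axis=0)
    scale = X_raw.std(axis=0, ddof=0)
    if np.any(scale == 0):
        const = [c for c, s in zip(covariates, scale) if s == 0]
        raise ValueError(f"constant covariate(s): {const}")
    # dummies are centered but left on their natural 0/1 scale
    binary = np.array([set(np.unique(X_raw[:, j])) <= {0.0, 1.0}
                       for j in range(X_raw.shape[1])])
    scale[binary] = 1.0
    X = np.column_stack([np.ones(len(df)), (X_raw - center) / scale])
    names = ["intercept"] + covariates

    subj_codes, _ = pd.factorize(df["subject_id"])
    n_subjects = int(subj_codes.max()) + 1
    nodes, weights = roots_hermite(n_nodes)

    x0 = np.zeros(X.shape[1] + 1)
    x0[-1] = np.log(0.5) if fixed_tau is None else np.log(max(fixed_tau, 1e-6))
    if fixed_tau is None:
        bounds = [(None, None)] * X.shape[1] + [(-6.0, 3.0)]
    else:
        bounds = [(None, None)] * X.shape[1] + [(x0[-1], x0[-1])]
    res = optimize.minimize(
        _agq_loglik, x0, args=(X, y, subj_codes, n_subjects, nodes, weights),
        method="L-BFGS-B", bounds=bounds,
        options={"ftol": 1e-12, "gtol": 1e-7, "maxiter": 1000},
    )
    params = res.x
    beta = params[:-1]
    if np.any(np.abs(beta) > SEPARATION_BOUND):
        bad = [n for n, b in zip(names, beta) if abs(b) > SEPARATION_BOUND]
        raise ValueError(
            f"separation detected (diverging coefficient for {bad}); "
            "consider penalized estimation"
        )
    if not res.success:
        logger.warning("error-model optimization did not fully converge: %s",
                       res.message)

    # Wald SEs from a numerical Hessian at the optimum (beta block only when
    # the variance is pinned)
    if fixed_tau is None:
        hess = _numerical_hessian(
            lambda p: _agq_loglik(p, X, y, subj_codes, n_subjects, nodes, weights),
            params,
        )
    else:
        hess = _numerical_hessian(
            lambda b: _agq_loglik(np.append(b, params[-1]), X, y, subj_codes,
                                  n_subjects, nodes, weights),
            beta,
        )
    cov = np.linalg.pinv(hess)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))[: len(beta)]

    coef = pd.Series(beta, index=names)
    se_s = pd.Series(se, index=names)
    z = 1.959963984540054
    return ErrorModelFit(
        odds_ratios=np.exp(coef.drop("intercept")),
        ci_low=np.exp(coef.drop("intercept") - z * se_s.drop("intercept")),
        ci_high=np.exp(coef.drop("intercept") + z * se_s.drop("intercept")),
        coef=coef,
        se=se_s,
        random_intercept_variance=float(np.exp(params[-1]) ** 2),
        loglik=float(-res.fun),
        n_obs=len(df),
        n_subjects=n_subjects,
        converged=bool(res.success),
        scaling=pd.DataFrame({"center": center, "scale": scale}, index=covariates),
    )


def _numerical_hessian(f, x, eps=1e-4):
    n = len(x)
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            xpp = x.copy(); xpp[i] += eps; xpp[j] += eps
            xpm = x.copy(); xpm[i] += eps; xpm[j] -= eps
            xmp = x.copy(); xmp[i] -= eps; xmp[j] += eps
            xmm = x.copy(); xmm[i] -= eps; xmm[j] -= eps
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * eps**2)
    return H
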