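"""Linear mixed models by maximum likelihood via EM.

Supports the random structures needed for the glucose-response model:
random intercepts grouped by subject (always), optional random slopes on
within-subject predictors, and an optional extra set of random intercepts
over the levels of a between-subject grouping variable (crossed with the
subject intercepts).

The marginal model for the stacked outcome y (glucose change, mmol/L) is

    y = X beta + Z b + eps,   b ~ N(0, G_full),  eps ~ N(0, sigma2 I)

where G_full is block diagonal: one shared (1+s)x(1+s) covariance G per
subject (intercept + s slopes) and a scalar variance tau2 per extra-grouping
level.  Estimation is ML via EM treating b as missing data, with a GLS
update for beta each iteration; both steps are ascent steps on the marginal
log-likelihood, so the likelihood trace is non-decreasing (asserted on every
fit).  All n x n algebra is avoided through the Woodbury identity and the
matrix determinant lemma, so cost per iteration is O(q^3 + n q) with q the
total number of random effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import DesignMatrix

logger = logging.getLogger(__name__)

EM_TOL = 1e-8
EM_MAX_ITER = 500
VAR_FLOOR = 1e-10
#: relative slack allowed in the monotone-likelihood assertion (pure
#: floating-point noise, dominant only when sigma2 hits its floor)
MONOTONE_SLACK = 1e-6


@dataclass(frozen=True)
class RandomSpec:
    """Random-effect structure: which design columns get random slopes and
    which between-subject variable (if any) forms an extra intercept
    grouping.  Subject intercepts are always present."""

    slope_terms: tuple[str, ...] = ()
    extra_grouping: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "slope_terms", tuple(self.slope_terms))

    @property
    def n_subject_effects(self) -> int:
        return 1 + len(self.slope_terms)

    def n_cov_params(self) -> int:
        k = self.n_subject_effects
        return k * (k + 1) // 2 + (1 if self.extra_grouping else 0)

    def is_nested_in(self, other: "RandomSpec") -> bool:
        slopes_ok = set(self.slope_terms) <= set(other.slope_terms)
        extra_ok = self.extra_grouping in (None, other.extra_grouping)
        return slopes_ok and extra_ok


@dataclass
class LMMFit:
    """A fitted linear mixed model (ML)."""

    beta: pd.Series            # fixed effects, first entry "intercept"
    se: pd.Series              # GLS standard errors of beta
    G: np.ndarray              # subject-level random-effect covariance
    tau2: float | None         # extra-grouping intercept variance
    sigma2: float              # residual variance, (mmol/L)^2
    loglik: float
    n_obs: int
    n_params: int
    converged: bool
    n_iter: int
    random_spec: RandomSpec
    columns: list[str]         # design columns (excluding intercept)
    blups: dict = field(default_factory=dict)        # subject -> effect vector
    extra_blups: dict = field(default_factory=dict)  # level -> intercept
    fixed_linpred: np.ndarray | None = None          # X beta on training rows
    loglik_trace: np.ndarray | None = None

    @property
    def intercept_var(self) -> float:
        return float(self.G[0, 0])


class MixedModelWorkspace:
    """Precomputed quantities for EM / penalized fitting on one dataset.

    Holds the fixed design (with leading intercept column), the sparse-ish
    random-effect design Z, and the block bookkeeping needed to tie the
    per-subject covariance parameters together.
    """

    def __init__(self, design: DesignMatrix, random_spec: RandomSpec,
                 check_rank: bool = True):
        self.random_spec = random_spec
        self.columns = list(design.X.columns)
        for term in random_spec.slope_terms:
            if term not in self.columns:
                raise ValueError(f"random slope term {term!r} not among design columns")
        X_raw = design.X.to_numpy(float)
        self.n, self.p = X_raw.shape
        self.X = np.column_stack([np.ones(self.n), X_raw])
        self.y = design.y.to_numpy(float)
        self.beta_names = ["intercept"] + self.columns

        groups = design.groups.to_numpy()
        self.group_labels = list(pd.unique(groups))
        self.m = len(self.group_labels)
        if self.m < 1:
            raise ValueError("no subjects in design")
        if self.m == 1:
            # degenerate but permitted: validation protocols can face a
            # single training subject; variance components are then barely
            # identified
            logger.warning("fitting a mixed model with a single subject")
        gidx = pd.Series(range(self.m), index=self.group_labels)[groups].to_numpy()

        if check_rank:
            self._check_rank()

        k = random_spec.n_subject_effects
        self.k = k
        slope_cols = [self.columns.index(t) for t in random_spec.slope_terms]
        if random_spec.extra_grouping:
            if random_spec.extra_grouping not in self.columns:
                raise ValueError(
                    f"extra grouping variable {random_spec.extra_grouping!r} not in design"
                )
            levels_raw = design.X[random_spec.extra_grouping].to_numpy()
            self.extra_levels = list(pd.unique(levels_raw))
            self.L = len(self.extra_levels)
            lidx = pd.Series(range(self.L), index=self.extra_levels)[levels_raw].to_numpy()
        else:
            self.extra_levels, self.L, lidx = [], 0, None

        self.q = self.m * k + self.L
        Z = np.zeros((self.n, self.q))
        rows = np.arange(self.n)
        Z[rows, gidx * k] = 1.0
        for j, col in enumerate(slope_cols, start=1):
            Z[rows, gidx * k + j] = X_raw[:, col]
        if self.L:
            Z[rows, self.m * k + lidx] = 1.0
        self.Z = Z
        self.ZtZ = Z.T @ Z
        self.ZtX = Z.T @ self.X
        self.Zty = Z.T @ self.y
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)

        # per-subject static cross-products for the PX-EM M-step
        self._rows = [np.flatnonzero(gidx == i) for i in range(self.m)]
        self._MtM, self._XtM, self._Mty, self._PtE = [], [], [], []
        Ze = Z[:, self.m * k:] if self.L else None
        for i, r in enumerate(self._rows):
            Mi = Z[np.ix_(r, range(i * k, (i + 1) * k))]
            self._MtM.append(Mi.T @ Mi)
            self._XtM.append(self.X[r].T @ Mi)
            self._Mty.append(Mi.T @ self.y[r])
            self._PtE.append(Mi.T @ Ze[r] if self.L else None)
        if self.L:
            self._XtZe = self.X.T @ Ze
            self._Zety = Ze.T @ self.y
            self._Ze_counts = Ze.sum(axis=0)

    def _check_rank(self):
        Xc = self.X[:, 1:] - self.X[:, 1:].mean(axis=0)
        if Xc.shape[1] == 0:
            return
        scale = np.linalg.norm(Xc, axis=0)
        scale[scale == 0] = 1.0
        R = np.linalg.qr(Xc / scale, mode="r")
        small = np.abs(np.diag(R)) < 1e-8
        if small.any():
            bad = [self.columns[i] for i in np.flatnonzero(small)]
            raise ValueError(f"design is rank deficient; collinear column(s): {bad}")

    # ---- parameter-dependent pieces -------------------------------------

    def _g_full_inv_logdet(self, G, tau2):
        """Inverse and log-determinant of the block-diagonal G_full."""
        w, U = np.linalg.eigh(G)
        w = np.maximum(w, VAR_FLOOR)
        Ginv = (U / w) @ U.T
        logdet_G = float(np.sum(np.log(w)))
        Ginv_full = np.zeros((self.q, self.q))
        k = self.k
        for i in range(self.m):
            Ginv_full[i * k:(i + 1) * k, i * k:(i + 1) * k] = Ginv
        logdet = self.m * logdet_G
        if self.L:
            t = max(tau2, VAR_FLOOR)
            idx = np.arange(self.m * k, self.q)
            Ginv_full[idx, idx] = 1.0 / t
            logdet += self.L * np.log(t)
        return Ginv_full, logdet

    def posterior(self, beta, G, tau2, sigma2):
        """Posterior mean/covariance of b given y, plus cached pieces."""
        Ginv_full, logdet_G = self._g_full_inv_logdet(G, tau2)
        A = Ginv_full + self.ZtZ / sigma2
        C = np.linalg.inv(A)
        Ztr = self.Zty - self.ZtX @ beta
        bhat = C @ Ztr / sigma2
        return bhat, C, Ztr, logdet_G, A

    def loglik(self, beta, G, tau2, sigma2, cache=None):
        bhat, C, Ztr, logdet_G, A = cache or self.posterior(beta, G, tau2, sigma2)
        sign, logdet_A = np.linalg.slogdet(A)
        logdet_V = self.n * np.log(sigma2) + logdet_G + logdet_A
        r2 = (self.y - self.X @ beta) @ (self.y - self.X @ beta)
        quad = r2 / sigma2 - Ztr @ C @ Ztr / sigma2**2
        return -0.5 * (self.n * np.log(2 * np.pi) + logdet_V + quad)

    def gls_beta(self, G, tau2, sigma2):
        """GLS fixed effects and their covariance at given variance params."""
        Ginv_full, _ = self._g_full_inv_logdet(G, tau2)
        C = np.linalg.inv(Ginv_full + self.ZtZ / sigma2)
        XtVX = (self.XtX - self.ZtX.T @ C @ self.ZtX / sigma2) / sigma2
        XtVy = (self.Xty - self.ZtX.T @ C @ self.Zty / sigma2) / sigma2
        cov = np.linalg.inv(XtVX)
        return cov @ XtVy, cov

    def em_variance_update(self, beta, G, tau2, sigma2, cache=None):
        """One EM M-step for (G, tau2, sigma2) with beta held fixed."""
        bhat, C, _, _, _ = cache or self.posterior(beta, G, tau2, sigma2)
        k = self.k
        S = np.zeros((k, k))
        for i in range(self.m):
            sl = slice(i * k, (i + 1) * k)
            S += np.outer(bhat[sl], bhat[sl]) + C[sl, sl]
        G_new = S / self.m
        if self.L:
            idx = np.arange(self.m * k, self.q)
            tau2_new = float(np.mean(bhat[idx] ** 2 + C[idx, idx]))
        else:
            tau2_new = None
        resid = self.y - self.X @ beta - self.Z @ bhat
        sigma2_new = float((resid @ resid + np.trace(C @ self.ZtZ)) / self.n)
        return G_new, tau2_new, max(sigma2_new, VAR_FLOOR)

    def px_em_update(self, beta, G, tau2, sigma2, cache=None):
        """One parameter-expanded EM (PX-EM) M-step.

        The complete-data model is expanded with a working k x k matrix
        multiplying the subject effects (and a working scalar on the extra
        intercepts); the M-step then solves jointly for the fixed effects
        and the working parameters by expected least squares, and the
        reduction maps the expanded estimates back to (G, tau2).  This is
        the standard acceleration for slow EM convergence of variance
        components; each step still increases the marginal likelihood.
        Returns ``None`` when the expanded normal equations are singular
        (e.g. variance components at the floor).
        """
        bhat, C, _, _, _ = cache or self.posterior(beta, G, tau2, sigma2)
        S = np.outer(bhat, bhat) + C
        k, p1 = self.k, self.X.shape[1]
        ne = 1 if self.L else 0
        D = p1 + k * k + ne
        A = np.zeros((D, D))
        a = np.zeros(D)
        ib = slice(0, p1)
        iL = slice(p1, p1 + k * k)
        A[ib, ib] = self.XtX
        a[:p1] = self.Xty
        Gstar = np.zeros((k, k))
        eidx = np.arange(self.m * k, self.q)
        for i in range(self.m):
            sl = slice(i * k, (i + 1) * k)
            bi = bhat[sl]
            Sii = S[sl, sl]
            Gstar += Sii
            A[ib, iL] += np.kron(bi[None, :], self._XtM[i])
            A[iL, iL] += np.kron(Sii, self._MtM[i])
            a[p1:p1 + k * k] += np.outer(self._Mty[i], bi).flatten(order="F")
            if ne:
                Sei = S[eidx, sl]  # L x k
                A[iL, -1] += (self._PtE[i] @ Sei).flatten(order="F")
        Gstar /= self.m
        if ne:
            chat = bhat[eidx]
            See = S[np.ix_(eidx, eidx)]
            A[ib, -1] = self._XtZe @ chat
            A[-1, -1] = float(self._Ze_counts @ np.diag(See))
            a[-1] = float(self._Zety @ chat)
        A = np.triu(A) + np.triu(A, 1).T
        try:
            u = np.linalg.solve(A, a)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(u)):
            return None
        beta_new = u[:p1]
        Lam = u[p1:p1 + k * k].reshape(k, k, order="F")
        sigma2_new = max(float((self.yty - a @ u) / self.n), VAR_FLOOR)
        G_new = Lam @ Gstar @ Lam.T
        if ne:
            lam_e = float(u[-1])
            tau2_new = max(lam_e**2 * float(np.mean(np.diag(See))), VAR_FLOOR)
        else:
            tau2_new = None
        return beta_new, G_new, tau2_new, sigma2_new


def fit_lmm(design: DesignMatrix, random_spec: RandomSpec = RandomSpec(),
            max_iter: int = EM_MAX_ITER, tol: float = EM_TOL,
            init: "LMMFit | None" = None) -> LMMFit:
    """Fit the mixed model by ML-EM.

    Iterates (E-step; variance M-step; GLS update of beta) until the
    relative log-likelihood change falls below ``tol`` or ``max_iter``
    iterations.  The likelihood trace is checked to be non-decreasing.
    ``init`` warm-starts the variance parameters from a previous fit with
    the same structure (validation loops refit on near-identical data).
    """
    ws = MixedModelWorkspace(design, random_spec)
    if (
        init is not None
        and init.random_spec == random_spec
        and init.columns == ws.columns
    ):
        G = init.G.copy()
        tau2 = init.tau2
        sigma2 = init.sigma2
        beta, _ = ws.gls_beta(G, tau2, sigma2)
    else:
        # initial values: OLS beta, residual variance split equally
        beta, _ = ws.gls_beta(np.eye(ws.k) * 1e-6, 1e-6, 1.0)
        resid = ws.y - ws.X @ beta
        s2 = float(resid @ resid / max(ws.n - ws.X.shape[1], 1))
        s2 = max(s2, VAR_FLOOR)
        G = np.eye(ws.k) * (s2 / 2)
        for j, term in enumerate(random_spec.slope_terms, start=1):
            sd = float(design.X[term].std()) or 1.0
            G[j, j] = s2 / (2 * sd**2)
        tau2 = s2 / 2 if ws.L else None
        sigma2 = s2 / 2

    trace = []
    ll = ws.loglik(beta, G, tau2, sigma2)
    trace.append(ll)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        cache = ws.posterior(beta, G, tau2, sigma2)
        step = ws.px_em_update(beta, G, tau2, sigma2, cache)
        ll_new = None
        if step is not None:
            beta_c, G_c, tau2_c, sigma2_c = step
            beta_c, _ = ws.gls_beta(G_c, tau2_c, sigma2_c)
            ll_c = ws.loglik(beta_c, G_c, tau2_c, sigma2_c)
            if np.isfinite(ll_c) and ll_c >= ll - MONOTONE_SLACK * (abs(ll) + 1):
                beta, G, tau2, sigma2, ll_new = beta_c, G_c, tau2_c, sigma2_c, ll_c
        if ll_new is None:
            # plain EM step (always an ascent step) when PX-EM is unusable
            G_c, tau2_c, sigma2_c = ws.em_variance_update(beta, G, tau2, sigma2, cache)
            beta_c, _ = ws.gls_beta(G_c, tau2_c, sigma2_c)
            ll_c = ws.loglik(beta_c, G_c, tau2_c, sigma2_c)
            if ll_c + MONOTONE_SLACK * (abs(ll) + 1) < ll:
                if sigma2_c <= 100 * VAR_FLOOR or sigma2 <= 100 * VAR_FLOOR:
                    # residual variance at the floor (degenerate noiseless
                    # data): the likelihood diverges and float noise breaks
                    # monotonicity; keep the current parameters and stop
                    converged = True
                    break
                raise AssertionError(
                    f"EM log-likelihood decreased at iteration {it}: "
                    f"{ll:.8g} -> {ll_c:.8g}"
                )
            beta, G, tau2, sigma2, ll_new = beta_c, G_c, tau2_c, sigma2_c, ll_c
        trace.append(ll_new)
        if abs(ll_new - ll) < tol * (abs(ll) + 1):
            converged = True
            ll = ll_new
            break
        ll = ll_new
    if not converged:
        logger.warning("EM did not converge in %d iterations", max_iter)

    beta, beta_cov = ws.gls_beta(G, tau2, sigma2)
    bhat, _, _, _, _ = ws.posterior(beta, G, tau2, sigma2)
    k = ws.k
    blups = {
        lab: bhat[i * k:(i + 1) * k].copy() for i, lab in enumerate(ws.group_labels)
    }
    extra_blups = {
        lev: float(bhat[ws.m * k + j]) for j, lev in enumerate(ws.extra_levels)
    }
    n_params = len(beta) + random_spec.n_cov_params() + 1
    return LMMFit(
        beta=pd.Series(beta, index=ws.beta_names),
        se=pd.Series(np.sqrt(np.diag(beta_cov)), index=ws.beta_names),
        G=G,
        tau2=tau2,
        sigma2=sigma2,
        loglik=float(ll),
        n_obs=ws.n,
        n_params=n_params,
        converged=converged,
        n_iter=it,
        random_spec=random_spec,
        columns=ws.columns,
        blups=blups,
        extra_blups=extra_blups,
        fixed_linpred=ws.X @ beta,
        loglik_trace=np.asarray(trace),
    )


def likelihood_ratio_test(fit_null: LMMFit, fit_alt: LMMFit):
    """LR test of nested mixed models fit to the same rows.

    Returns ``(lr, df, p)`` with the LR statistic floored at zero and the
    p-value from a chi-square with df = difference in parameter count.  For
    variance-component tests on the boundary this reference distribution is
    conservative.
    """
    if fit_null.n_obs != fit_alt.n_obs:
        raise ValueError("models were fit to different data (n_obs differ)")
    cols_nested = set(fit_null.columns) <= set(fit_alt.columns)
    if not (cols_nested and fit_null.random_spec.is_nested_in(fit_alt.random_spec)):
        raise ValueError("fit_null is not nested in fit_alt")
    if fit_null.n_params > fit_alt.n_params:
        raise ValueError("null model has more parameters than the alternative")
    lr = max(2.0 * (fit_alt.loglik - fit_null.loglik), 0.0)
    df = fit_alt.n_params - fit_null.n_params
    p = float(stats.chi2.sf(lr, df)) if df > 0 else (1.0 if lr == 0 else 0.0)
    return lr, df, p


def bic(fit: LMMFit) -> float:
    """Bayesian information criterion: -2 loglik + n_params log(n_obs)."""
    if fit.n_obs == 0:
        return 0.0
    return -2.0 * fit.loglik + fit.n_params * np.log(fit.n_obs)


def r2_nakagawa(fit: LMMFit) -> tuple[float, float]:
    """Marginal and conditional R^2 for a random-intercepts-only fit.

    marginal   = var(X beta) / (var(X beta) + intercept var + residual var)
    conditional adds the intercept variance to the numerator.  Random slopes
    (or extra grouping intercepts) are not supported — refit with intercepts
    only.
    """
    if fit.random_spec.slope_terms or fit.random_spec.extra_grouping:
        raise ValueError("intercepts-only required: refit without random slopes/groupings")
    var_f = float(np.var(fit.fixed_linpred))
    var_a = fit.intercept_var
    total = var_f + var_a + fit.sigma2
    return var_f / total, (var_f + var_a) / total


def predict(fit: LMMFit, new_rows: pd.DataFrame, use_random: bool = True) -> np.ndarray:
    """Predict glucose change (mmol/L) for new session rows.

    Adds the subject's estimated random effects (and extra-grouping level
    effect) when ``use_random`` and the subject/level appeared in training;
    unseen subjects get the population prediction.  ``new_rows`` must carry
    every model column plus ``subject_id``.
    """
    missing = [c for c in fit.columns if c not in new_rows.columns]
    if missing:
        raise ValueError(f"new rows lack model column(s): {missing}")
    X = new_rows[fit.columns].to_numpy(float)
    eta = fit.beta.iloc[0] + X @ fit.beta.iloc[1:].to_numpy()
    if not use_random:
        return eta
    eta = eta.copy()
    slope_idx = [fit.columns.index(t) for t in fit.random_spec.slope_terms]
    for r, sid in enumerate(new_rows["subject_id"].to_numpy()):
        b = fit.blups.get(sid)
        if b is not None:
            eta[r] += b[0] + sum(
                b[j + 1] * X[r, ci] for j, ci in enumerate(slope_idx)
            )
    if fit.random_spec.extra_grouping:
        levels = new_rows[fit.random_spec.extra_grouping].to_numpy()
        for r, lev in enumerate(levels):
            eta[r] += fit.extra_blups.get(lev, 0.0)
    return eta
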