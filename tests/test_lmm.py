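import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from exglyc.lmm import (
    RandomSpec,
    bic,
    fit_lmm,
    likelihood_ratio_test,
    predict,
    r2_nakagawa,
)

from conftest import make_design, simulate_lmm


def direct_marginal_loglik(design, slope_col=None):
    """Oracle: maximize the dense marginal Gaussian likelihood numerically.

    Parameterized by the Cholesky factor of the random-effect covariance
    and log residual SD; beta profiled out by GLS.  Independent of the EM
    implementation.
    """
    X = np.column_stack([np.ones(len(design)), design.X.to_numpy(float)])
    y = design.y.to_numpy(float)
    groups = design.groups.to_numpy()
    labels = pd.unique(groups)
    k = 1 if slope_col is None else 2

    def neg_ll(theta):
        L = np.zeros((k, k))
        idx = np.tril_indices(k)
        L[idx] = theta[:-1]
        G = L @ L.T
        s2 = np.exp(theta[-1]) ** 2
        V = np.zeros((len(y), len(y)))
        for lab in labels:
            r = np.flatnonzero(groups == lab)
            Z = np.ones((len(r), k))
            if k == 2:
                Z[:, 1] = design.X.iloc[r, slope_col]
            V[np.ix_(r, r)] = Z @ G @ Z.T
        V[np.diag_indices_from(V)] += s2
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        r = y - X @ beta
        sign, logdet = np.linalg.slogdet(V)
        return 0.5 * (len(y) * np.log(2 * np.pi) + logdet + r @ Vi @ r)

    x0 = np.full(k * (k + 1) // 2 + 1, 0.3)
    best = np.inf
    for scale in (0.5, 1.0, 2.0):
        res = optimize.minimize(neg_ll, x0 * scale, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 20000, "maxfev": 20000})
        best = min(best, res.fun)
    return -best


class TestFitLMM:
    def test_noiseless_identifiability(self):
        rng = np.random.default_rng(0)
        d = simulate_lmm(rng, 6, 5, beta0=1.5, beta=[-0.4, 0.2],
                         intercept_sd=0.0, slope_sd=0.0, residual_sd=0.0)
        fit = fit_lmm(d)
        assert np.allclose(fit.beta.to_numpy(), [1.5, -0.4, 0.2], atol=1e-6)

    def test_loglik_matches_direct_optimizer_on_toy(self):
        rng = np.random.default_rng(1)
        d = simulate_lmm(rng, 5, 4, beta0=0.5, beta=[-0.3], intercept_sd=0.8,
                         slope_sd=0.0, residual_sd=0.6)
        fit = fit_lmm(d)
        oracle = direct_marginal_loglik(d)
        assert fit.loglik == pytest.approx(oracle, abs=1e-4)

    def test_loglik_matches_direct_optimizer_with_slope(self):
        rng = np.random.default_rng(2)
        d = simulate_lmm(rng, 8, 6, beta0=0.0, beta=[0.5], intercept_sd=0.7,
                         slope_sd=0.4, residual_sd=0.5)
        fit = fit_lmm(d, RandomSpec(slope_terms=("x0",)))
        oracle = direct_marginal_loglik(d, slope_col=0)
        assert fit.loglik >= oracle - 1e-4

    def test_parameter_recovery_within_3se(self):
        rng = np.random.default_rng(3)
        d = simulate_lmm(rng, 100, 8, beta0=1.0, beta=[-0.46, 0.24],
                         intercept_sd=0.8, slope_sd=0.3, residual_sd=1.0,
                         corr=-0.3)
        fit = fit_lmm(d, RandomSpec(slope_terms=("x0",)))
        truth = np.array([1.0, -0.46, 0.24])
        assert np.all(np.abs(fit.beta.to_numpy() - truth) < 3 * fit.se.to_numpy())
        assert fit.G[0, 0] == pytest.approx(0.64, rel=0.40)
        assert fit.G[1, 1] == pytest.approx(0.09, rel=0.40)
        assert fit.sigma2 == pytest.approx(1.0, rel=0.25)

    def test_em_loglik_trace_monotone(self):
        rng = np.random.default_rng(4)
        d = simulate_lmm(rng, 15, 5, beta0=0.0, beta=[1.0, -1.0],
                         intercept_sd=0.5, slope_sd=0.2, residual_sd=0.8)
        fit = fit_lmm(d, RandomSpec(slope_terms=("x1",)), )
        diffs = np.diff(fit.loglik_trace)
        assert np.all(diffs > -1e-6 * (np.abs(fit.loglik) + 1))

    def test_group_label_invariance(self):
        rng = np.random.default_rng(5)
        d = simulate_lmm(rng, 10, 4, beta0=0.3, beta=[0.7], intercept_sd=0.6,
                         slope_sd=0.0, residual_sd=0.5)
        relabeled = make_design(
            d.X, d.y, [f"Z-{g}" for g in d.groups], d.session_number
        )
        f1, f2 = fit_lmm(d), fit_lmm(relabeled)
        assert np.allclose(f1.beta, f2.beta, atol=1e-10)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-8)

    def test_collinear_columns_named(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame({"a": rng.normal(size=20)})
        X["b"] = 2.0 * X["a"]
        d = make_design(X, rng.normal(size=20), ["g1"] * 10 + ["g2"] * 10)
        with pytest.raises(ValueError, match="collinear"):
            fit_lmm(d)

    def test_agrees_with_statsmodels_mixedlm(self):
        rng = np.random.default_rng(7)
        d = simulate_lmm(rng, 20, 6, beta0=0.5, beta=[-0.4, 0.3],
                         intercept_sd=0.7, slope_sd=0.0, residual_sd=0.9)
        fit = fit_lmm(d)
        import statsmodels.formula.api as smf

        df = d.to_frame().rename(columns={"delta_glucose": "y"})
        sm_fit = smf.mixedlm("y ~ x0 + x1", df, groups=df["subject_id"]).fit(reml=False)
        assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-4)
        assert np.allclose(fit.beta.to_numpy(), sm_fit.fe_params.to_numpy(), atol=1e-3)


@pytest.fixture(scope="module")
def lr_fits():
    rng = np.random.default_rng(8)
    d = simulate_lmm(rng, 20, 6, beta0=0.0, beta=[0.6], intercept_sd=0.6,
                     slope_sd=0.3, residual_sd=0.7)
    return fit_lmm(d), fit_lmm(d, RandomSpec(slope_terms=("x0",)))


class TestLikelihoodRatio:
    def test_self_comparison_is_null(self, lr_fits):
        null, _ = lr_fits
        lr, df, p = likelihood_ratio_test(null, null)
        assert lr == 0.0 and p == 1.0

    def test_slope_adds_two_parameters(self, lr_fits):
        null, alt = lr_fits
        lr, df, p = likelihood_ratio_test(null, alt)
        assert df == 2
        assert lr >= 0.0

    def test_non_nested_rejected(self, lr_fits):
        null, alt = lr_fits
        with pytest.raises(ValueError):
            likelihood_ratio_test(alt, null)

    def test_different_data_rejected(self, lr_fits):
        null, _ = lr_fits
        rng = np.random.default_rng(9)
        other = fit_lmm(simulate_lmm(rng, 10, 4, beta0=0, beta=[0.1],
                                     intercept_sd=0.3, slope_sd=0, residual_sd=0.5))
        with pytest.raises(ValueError):
            likelihood_ratio_test(other, null)

    def test_lr_invariant_to_predictor_rescaling(self):
        rng = np.random.default_rng(10)
        d = simulate_lmm(rng, 15, 5, beta0=0.0, beta=[0.5], intercept_sd=0.5,
                         slope_sd=0.2, residual_sd=0.6)
        scaled = make_design(d.X * 7.5, d.y, d.groups, d.session_number)
        lr1, *_ = likelihood_ratio_test(
            fit_lmm(d), fit_lmm(d, RandomSpec(slope_terms=("x0",)))
        )
        lr2, *_ = likelihood_ratio_test(
            fit_lmm(scaled), fit_lmm(scaled, RandomSpec(slope_terms=("x0",)))
        )
        assert lr1 == pytest.approx(lr2, abs=1e-4)


class TestBIC:
    def test_extra_parameter_costs_log_n(self):
        rng = np.random.default_rng(11)
        d = simulate_lmm(rng, 12, 5, beta0=0.2, beta=[0.4, 0.0],
                         intercept_sd=0.5, slope_sd=0.0, residual_sd=0.6)
        f_small = fit_lmm(make_design(d.X[["x0"]], d.y, d.groups, d.session_number))
        f_big = fit_lmm(d)
        expected = (
            -2 * (f_big.loglik - f_small.loglik)
            + (f_big.n_params - f_small.n_params) * np.log(f_big.n_obs)
        )
        assert bic(f_big) - bic(f_small) == pytest.approx(expected, abs=1e-10)
        assert f_big.n_params - f_small.n_params == 1

    def test_bic_hand_computation(self):
        rng = np.random.default_rng(12)
        d = simulate_lmm(rng, 5, 4, beta0=0.5, beta=[-0.3], intercept_sd=0.8,
                         slope_sd=0.0, residual_sd=0.6)
        fit = fit_lmm(d)
        assert bic(fit) == pytest.approx(
            -2 * fit.loglik + fit.n_params * np.log(20), abs=1e-6
        )


class TestNakagawaR2:
    def test_marginal_never_exceeds_conditional(self):
        rng = np.random.default_rng(13)
        for seed in range(3):
            d = simulate_lmm(np.random.default_rng(seed), 15, 5, beta0=0.0,
                             beta=[0.5], intercept_sd=0.6, slope_sd=0.0,
                             residual_sd=0.8)
            m, c = r2_nakagawa(fit_lmm(d))
            assert 0.0 <= m <= c <= 1.0

    def test_no_subject_variance_gives_equality(self):
        rng = np.random.default_rng(14)
        d = simulate_lmm(rng, 20, 10, beta0=0.0, beta=[1.0], intercept_sd=0.0,
                         slope_sd=0.0, residual_sd=0.5)
        m, c = r2_nakagawa(fit_lmm(d))
        assert c - m < 0.02  # fitted intercept variance is near zero

    def test_null_fixed_effects_give_zero_marginal(self):
        rng = np.random.default_rng(15)
        d = simulate_lmm(rng, 20, 6, beta0=0.0, beta=[0.0], intercept_sd=0.8,
                         slope_sd=0.0, residual_sd=0.5)
        m, c = r2_nakagawa(fit_lmm(d))
        assert m < 0.02
        assert c > 0.5  # intercept variance dominates

    def test_configured_variance_ratios_recovered(self):
        # fixed:intercept:residual variance = 2:1:1 -> R2 0.50 / 0.75
        rng = np.random.default_rng(16)
        d = simulate_lmm(rng, 500, 10, beta0=0.0, beta=[np.sqrt(2.0)],
                         intercept_sd=1.0, slope_sd=0.0, residual_sd=1.0)
        m, c = r2_nakagawa(fit_lmm(d))
        assert m == pytest.approx(0.50, abs=0.03)
        assert c == pytest.approx(0.75, abs=0.03)

    def test_requires_intercepts_only(self):
        rng = np.random.default_rng(17)
        d = simulate_lmm(rng, 10, 5, beta0=0.0, beta=[0.5], intercept_sd=0.5,
                         slope_sd=0.2, residual_sd=0.6)
        with pytest.raises(ValueError, match="intercepts-only"):
            r2_nakagawa(fit_lmm(d, RandomSpec(slope_terms=("x0",))))


@pytest.fixture(scope="module")
def intercept_fit():
    rng = np.random.default_rng(18)
    d = simulate_lmm(rng, 12, 6, beta0=0.4, beta=[-0.5], intercept_sd=1.0,
                     slope_sd=0.0, residual_sd=0.4)
    return fit_lmm(d)


class TestPredict:
    def test_unseen_subject_gets_population_prediction(self, intercept_fit):
        rows = pd.DataFrame({"x0": [0.7], "subject_id": ["stranger"]})
        with_re = predict(intercept_fit, rows, use_random=True)
        without = predict(intercept_fit, rows, use_random=False)
        assert with_re[0] == without[0]

    def test_positive_blup_raises_prediction(self, intercept_fit):
        sid = max(intercept_fit.blups, key=lambda s: intercept_fit.blups[s][0])
        assert intercept_fit.blups[sid][0] > 0
        rows = pd.DataFrame({"x0": [0.0], "subject_id": [sid]})
        assert predict(intercept_fit, rows, True)[0] > predict(intercept_fit, rows, False)[0]

    def test_missing_column_rejected(self, intercept_fit):
        with pytest.raises(ValueError, match="x0"):
            predict(intercept_fit, pd.DataFrame({"subject_id": ["a"]}))

    def test_null_model_predicts_zero(self):
        rng = np.random.default_rng(19)
        d = simulate_lmm(rng, 6, 4, beta0=0.0, beta=[0.0], intercept_sd=0.0,
                         slope_sd=0.0, residual_sd=0.0)
        fit = fit_lmm(d)
        rows = pd.DataFrame({"x0": [2.0], "subject_id": ["S0"]})
        assert abs(predict(fit, rows, True)[0]) < 1e-8


class TestExtraGrouping:
    def test_grouping_intercepts_recover_level_variance(self):
        rng = np.random.default_rng(20)
        n_levels, subj_per_level, k = 8, 4, 6
        rows, ys, groups, levels = [], [], [], []
        for lev in range(n_levels):
            c = rng.normal(0, 1.0)
            for s in range(subj_per_level):
                b = rng.normal(0, 0.3)
                x = rng.normal(size=k)
                y = 0.5 * x + b + c + rng.normal(0, 0.5, k)
                rows.append(np.column_stack([x, np.full(k, float(lev))]))
                ys.append(y)
                groups += [f"L{lev}S{s}"] * k
        X = pd.DataFrame(np.vstack(rows), columns=["x0", "level"])
        d = make_design(X, np.concatenate(ys), groups)
        fit = fit_lmm(d, RandomSpec(extra_grouping="level"))
        assert fit.tau2 == pytest.approx(1.0, rel=0.8)  # 8 levels: noisy but present
        assert fit.tau2 > 5 * fit.G[0, 0] - 0.3  # level variance dominates subject variance
        null = fit_lmm(d)
        lr, df, p = likelihood_ratio_test(null, fit)
        assert df == 1 and lr > 0
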