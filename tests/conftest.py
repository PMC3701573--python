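import numpy as np
import pandas as pd
import pytest

from exglyc import CohortConfig, generate_cohort
from exglyc.features import DesignMatrix


@pytest.fixture(scope="session")
def small_cohort():
    """20 subjects x 6 sessions from the default generative model."""
    cfg = CohortConfig(n_subjects=20, sessions_per_subject=6, seed=42)
    subjects, sessions = generate_cohort(cfg)
    return subjects, sessions


@pytest.fixture(scope="session")
def tiny_cohort():
    """8 subjects x 4 sessions; enough to fit but fast to refit repeatedly."""
    cfg = CohortConfig(n_subjects=8, sessions_per_subject=4, seed=7)
    subjects, sessions = generate_cohort(cfg)
    return subjects, sessions


def make_design(X: pd.DataFrame, y, groups, session_number=None, t_max=420.0):
    """Hand-rolled DesignMatrix for toy problems."""
    n = len(X)
    return DesignMatrix(
        X=X.astype(float).reset_index(drop=True),
        y=pd.Series(np.asarray(y, float)),
        groups=pd.Series(list(groups)),
        session_number=pd.Series(
            np.asarray(session_number if session_number is not None else np.ones(n), int)
        ),
        t_max=t_max,
    )


def simulate_lmm(rng, n_subjects, n_sessions, beta0, beta, intercept_sd,
                 slope_sd, residual_sd, corr=0.0, x_means=None, x_sds=None,
                 slope_col=0):
    """Simulate from the mixed-model family for recovery/oracle tests.

    Returns a DesignMatrix with columns x0..x{p-1}; the random slope (if
    slope_sd > 0) applies to column ``slope_col``.
    """
    p = len(beta)
    x_means = np.zeros(p) if x_means is None else np.asarray(x_means, float)
    x_sds = np.ones(p) if x_sds is None else np.asarray(x_sds, float)
    cov = np.array(
        [[intercept_sd**2, corr * intercept_sd * slope_sd],
         [corr * intercept_sd * slope_sd, slope_sd**2]]
    )
    rows, ys, groups, snums = [], [], [], []
    for i in range(n_subjects):
        b = rng.multivariate_normal(np.zeros(2), cov)
        X = x_means + rng.standard_normal((n_sessions, p)) * x_sds
        eta = beta0 + X @ np.asarray(beta, float) + b[0] + b[1] * X[:, slope_col]
        y = eta + rng.normal(0, residual_sd, n_sessions)
        rows.append(X)
        ys.append(y)
        groups += [f"S{i}"] * n_sessions
        snums += list(range(1, n_sessions + 1))
    X = pd.DataFrame(np.vstack(rows), columns=[f"x{j}" for j in range(p)])
    return make_design(X, np.concatenate(ys), groups, snums)
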