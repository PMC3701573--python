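"""LMG relative importance of predictors, with bootstrap intervals.

The LMG decomposition (averaging each predictor's sequential contribution
to OLS R-squared over all orderings of entry) attributes the full-model
R-squared to individual predictors even when they are correlated.  Because
ordinary R-squared ignores repeated measures, shares are computed on
first-session rows only — one row per subject — matching how the method is
applied to the exercise cohort.

The all-orderings average is computed exactly over subsets: a predictor's
share is

    share_j = sum over S not containing j of w(|S|) * (R2(S + j) - R2(S)),
    w(s) = s! (p - 1 - s)! / p!

which needs 2^p R-squared evaluations rather than p! orderings.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
import pandas as pd

from .features import DesignMatrix


@dataclass
class ImportanceResult:
    shares: pd.Series                 # percent of outcome variance, per predictor
    total_r2: float                   # full-model R-squared (fraction)
    ci_low: pd.Series | None = None   # bootstrap percentile bounds, percent
    ci_high: pd.Series | None = None
    n_boot: int = 0
    n_skipped: int = 0                # degenerate bootstrap replicates
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"share_pct": self.shares})
        if self.ci_low is not None:
            out["ci_low_pct"] = self.ci_low
            out["ci_high_pct"] = self.ci_high
        return out


def first_sessions(design: DesignMatrix) -> DesignMatrix:
    """Restrict a design to each subject's first session (one row each)."""
    first = design.session_number.groupby(design.groups.values).transform("min")
    return design.subset((design.session_number == first).to_numpy())


def _r2_all_subsets(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS R-squared for every subset of columns, indexed by bitmask."""
    n, p = X.shape
    yc = y - y.mean()
    tss = float(yc @ yc)
    if tss == 0:
        raise ValueError("outcome is constant; R-squared undefined")
    Xc = X - X.mean(axis=0)
    r2 = np.empty(1 << p)
    r2[0] = 0.0
    for mask in range(1, 1 << p):
        cols = [j for j in range(p) if mask >> j & 1]
        coef, rss, rank, _ = np.linalg.lstsq(Xc[:, cols], yc, rcond=None)
        if rank < len(cols) or rss.size == 0:
            resid = yc - Xc[:, cols] @ coef
            rss_val = float(resid @ resid)
        else:
            rss_val = float(rss[0])
        r2[mask] = 1.0 - rss_val / tss
    return r2


def lmg_shares(design_first: DesignMatrix, predictors=None) -> ImportanceResult:
    """Exact LMG shares (percent) on first-session data.

    Predictors with no variance across subjects (e.g. session number, which
    is constant at the first session) are excluded from the decomposition
    and carry no share.  Shares sum to 100 x full-model R-squared.
    """
    counts = design_first.groups.value_counts()
    if (counts > 1).any():
        raise ValueError("first sessions only: found repeated sessions per subject")
    predictors = list(predictors) if predictors is not None else design_first.columns
    Xall = design_first.X[predictors]
    varying = [c for c in predictors if Xall[c].nunique() > 1]
    p = len(varying)
    if p == 0:
        raise ValueError("no predictor varies across first sessions")
    if p > 15:
        raise ValueError(f"subset enumeration limited to 15 predictors, got {p}")
    X = Xall[varying].to_numpy(float)
    y = design_first.y.to_numpy(float)

    r2 = _r2_all_subsets(X, y)
    full = 1 << p
    weights = np.array(
        [factorial(s) * factorial(p - 1 - s) / factorial(p) for s in range(p)]
    )
    shares = np.zeros(p)
    sizes = np.array([bin(m).count("1") for m in range(full)])
    for j in range(p):
        bit = 1 << j
        without = np.array([m for m in range(full) if not m & bit])
        shares[j] = float(
            np.sum(weights[sizes[without]] * (r2[without | bit] - r2[without]))
        )
    total = float(r2[full - 1])
    assert abs(shares.sum() - total) < 1e-6, "LMG shares must sum to the full-model R2"
    return ImportanceResult(
        shares=pd.Series(shares * 100.0, index=varying), total_r2=total
    )


def bootstrap_ci(design_first: DesignMatrix, predictors=None, n_boot: int = 1000,
                 seed: int = 0, alpha: float = 0.05) -> ImportanceResult:
    """Percentile bootstrap CIs for the LMG shares, resampling subjects.

    Subjects (the exchangeable unit — one first-session row each) are
    resampled with replacement; replicates with a constant outcome or no
    varying predictor are skipped and counted.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if len(design_first) < 2:
        raise ValueError("need at least 2 subjects to bootstrap")
    point = lmg_shares(design_first, predictors)
    rng = np.random.default_rng(seed)
    n = len(design_first)
    draws = np.full((n_boot, len(point.shares)), np.nan)
    n_skipped = 0
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot = design_first.subset(idx)
        # resampled rows are distinct draws, not repeated sessions
        boot.groups = pd.Series(np.arange(n))
        boot.session_number = pd.Series(np.ones(n, dtype=int))
        try:
            rep = lmg_shares(boot, predictors)
        except ValueError:
            n_skipped += 1
            continue
        draws[b] = rep.shares.reindex(point.shares.index).to_numpy()
    lo = np.nanpercentile(draws, 100 * alpha / 2, axis=0)
    hi = np.nanpercentile(draws, 100 * (1 - alpha / 2), axis=0)
    return ImportanceResult(
        shares=point.shares,
        total_r2=point.total_r2,
        ci_low=pd.Series(lo, index=point.shares.index),
        ci_high=pd.Series(hi, index=point.shares.index),
        n_boot=n_boot,
        n_skipped=n_skipped,
        seed=seed,
    )
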