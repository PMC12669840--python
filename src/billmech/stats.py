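"""Statistical tests: Procrustes ANOVA with permutation, Mann-Whitney U,
Spearman rank correlation.

Procrustes ANOVA fits a linear model to flattened Procrustes shape
coordinates and evaluates the effect sum of squares against a reference
distribution obtained by randomizing rows of the response (residual
randomization under the intercept-only reduced model).  The observed
statistic is included in the reference set, so p >= 1/(n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class ProcrustesAnovaResult:
    r_squared: float
    f_stat: float
    p_value: float
    n_permutations: int
    seed: int
    df_effect: int
    df_residual: int
    n: int


@dataclass
class RankTestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]


def _design_matrix(predictor: np.ndarray) -> np.ndarray:
    """Intercept + effect columns for a factor or a numeric covariate."""
    predictor = np.asarray(predictor)
    n = len(predictor)
    if predictor.dtype.kind in "fiu" and predictor.ndim == 1 and len(np.unique(predictor)) > 2:
        x = predictor.astype(float)
        if np.ptp(x) == 0:
            raise ValueError("constant predictor: effect undefined")
        return np.column_stack([np.ones(n), x - x.mean()])
    levels = np.unique(predictor)
    if len(levels) < 2:
        raise ValueError("constant predictor: effect undefined")
    cols = [np.ones(n)]
    for lv in levels[1:]:
        cols.append((predictor == lv).astype(float))
    return np.column_stack(cols)


def procrustes_anova(
    shape: np.ndarray,
    predictor,
    n_perm: int = 999,
    seed: int = 0,
) -> ProcrustesAnovaResult:
    """Permutational linear model of shape on one predictor.

    ``shape`` is (n, k, 3) or (n, p); ``predictor`` a length-n factor (any
    non-numeric or 2-level array) or numeric covariate.  R^2 is
    SS_effect/SS_total; F uses the standard degrees of freedom; the p-value is
    the proportion of row-permuted responses (observed included) whose F
    meets or exceeds the observed.
    """
    Y = np.asarray(shape, dtype=float)
    if Y.ndim == 3:
        Y = Y.reshape(Y.shape[0], -1)
    n = Y.shape[0]
    if n <= 2:
        raise ValueError("need n > 2 observations")
    X = _design_matrix(predictor)
    if X.shape[0] != n:
        raise ValueError("predictor length must match the number of specimens")

    rank = np.linalg.matrix_rank(X)
    df1 = rank - 1
    df2 = n - rank
    if df1 < 1 or df2 < 1:
        raise ValueError("insufficient degrees of freedom")

    H = X @ np.linalg.pinv(X)
    H0 = np.full((n, n), 1.0 / n)
    A = H - H0
    Yc = Y - Y.mean(axis=0)
    ss_total = float((Yc ** 2).sum())
    if ss_total <= 0:
        raise ValueError("response has no variation")
    ss_eff = float(((A @ Y) ** 2).sum())
    ss_res = ss_total - ss_eff
    r2 = ss_eff / ss_total
    # For a saturated model (zero residual) F is infinite; permutation
    # comparison still works through the SS_effect ordering.
    f_obs = (ss_eff / df1) / (ss_res / df2) if ss_res > 1e-12 * ss_total else np.inf

    rng = np.random.default_rng(seed)
    count = 1  # the observed permutation
    # F is a monotone function of SS_effect (SS_total is permutation-invariant),
    # so the permutation comparison runs on SS_effect, batched.
    chunk = max(1, min(n_perm, 200_000 // max(1, n * Y.shape[1])))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        perms = np.array([rng.permutation(n) for _ in range(b)])
        Yp = Y[perms]                      # (b, n, p)
        ss_p = np.einsum("ij,bjq->biq", A, Yp)
        ss_p = np.einsum("biq,biq->b", ss_p, ss_p)
        count += int(np.sum(ss_p >= ss_eff * (1.0 - 1e-12)))
        done += b
    p = count / (n_perm + 1)
    return ProcrustesAnovaResult(
        r_squared=r2, f_stat=f_obs, p_value=p, n_permutations=n_perm,
        seed=seed, df_effect=df1, df_residual=df2, n=n,
    )


def mann_whitney_u(x, y, alternative: str = "two-sided") -> RankTestResult:
    """Mann-Whitney U test; exact when n*m <= 400 with no ties, otherwise
    normal approximation with tie correction.  The statistic W is the U of
    the first sample (0 <= W <= n*m)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    nm = len(x) * len(y)
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (nm <= 400 and not has_ties) else "approximate"
    if method == "approximate" and np.ptp(np.concatenate([x, y])) == 0:
        # all observations identical: tie-corrected variance is zero; no
        # evidence either way
        return RankTestResult(statistic=nm / 2.0, p_value=1.0,
                              method=method, n=(len(x), len(y)))
    res = sps.mannwhitneyu(
        x, y, alternative=alternative,
        method="exact" if method == "exact" else "asymptotic",
    )
    return RankTestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                          method=method, n=(len(x), len(y)))


def spearman(x, y) -> RankTestResult:
    """Spearman rank correlation (Pearson correlation of mid-ranks); p-value
    from the t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.ptp(sps.rankdata(x)) == 0 or np.ptp(sps.rankdata(y)) == 0:
        raise ValueError("zero rank variance: correlation undefined")
    res = sps.spearmanr(x, y)
    p = float(res.pvalue)
    r = float(res.statistic)
    if abs(r) == 1.0:
        p = 0.0 if np.isnan(p) else p
    return RankTestResult(statistic=r, p_value=p, method="t-approximation",
                          n=(len(x),))
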