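"""Shared rank-correlation routines.

Spearman correlation is computed as Pearson on mid-ranks (average ranks for
ties).  Two-sided p values use the t approximation
``t = rho * sqrt((n-2)/(1-rho^2))`` with n-2 degrees of freedom; for small
samples (n <= 9) without ties the exact permutation distribution of rho is
enumerated instead, matching the group sizes at which the approximation is
poorest.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
from scipy import stats


def _rank_rows(x: np.ndarray) -> np.ndarray:
    """Mid-ranks along the last axis (1-based, ties averaged)."""
    return stats.rankdata(x, axis=-1)


def spearman_rho_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Spearman correlations between rows of ``x`` and rows of ``y``.

    Parameters
    ----------
    x : (p, n) array
    y : (q, n) array

    Returns
    -------
    (p, q) array of correlations; rows with zero rank variance give NaN.
    """
    rx = _rank_rows(np.asarray(x, dtype=float))
    ry = _rank_rows(np.asarray(y, dtype=float))
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    sx = np.sqrt((rx ** 2).sum(axis=1))
    sy = np.sqrt((ry ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx @ ry.T) / np.outer(sx, sy)
    rho[:, sy == 0] = np.nan
    rho[sx == 0, :] = np.nan
    return np.clip(rho, -1.0, 1.0, out=rho)


def spearman_p_from_rho(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p via the t approximation (vectorized)."""
    rho = np.asarray(rho, dtype=float)
    if n < 3:
        return np.full_like(rho, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(rho), 1.0), 0.0, p)
    return np.where(np.isnan(rho), np.nan, np.minimum(p, 1.0))


def _exact_spearman_p(rho_obs: float, y_ranks: np.ndarray) -> float:
    """Exact two-sided permutation p for |rho| >= |rho_obs| (n <= 9)."""
    n = len(y_ranks)
    base = np.arange(1, n + 1, dtype=float)
    yc = y_ranks - y_ranks.mean()
    sy = np.sqrt((yc ** 2).sum())
    sx = np.sqrt(((base - base.mean()) ** 2).sum())
    count = 0
    total = 0
    target = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(base):
        r = ((np.asarray(perm) - base.mean()) @ yc) / (sx * sy)
        if abs(r) >= target:
            count += 1
        total += 1
    return count / total


def spearman(x, y, exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman correlation with two-sided p for two 1-d vectors.

    Exact permutation p when n <= ``exact_max_n`` and neither vector has
    ties; t approximation otherwise.  Constant input yields (nan, nan) with
    a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman rho undefined")
        return float("nan"), float("nan")
    rho = float(spearman_rho_matrix(x[None, :], y[None, :])[0, 0])
    no_ties = (len(np.unique(x)) == n) and (len(np.unique(y)) == n)
    if n <= exact_max_n and no_ties:
        p = _exact_spearman_p(rho, _rank_rows(y))
    else:
        p = float(spearman_p_from_rho(np.array([rho]), n)[0])
    return rho, p


def welch_t_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided Welch t-test p values per row of two (p, n) matrices.

    Rows where both groups are constant with equal means get p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
    p = np.where(degenerate & equal_means, 1.0, p)
    p = np.where(degenerate & ~equal_means, 0.0, p)
    return p
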