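"""Cross-organ trajectory clustering with fuzzy c-means.

Each (feature, tissue) pair contributes one trajectory — the mean rpmm per
timepoint, z-scored — and trajectories from all organs are clustered
together (Mfuzz-style soft clustering with Bezdek membership updates).
The number of clusters is chosen from the minimum-centroid-distance curve:
the smallest pairwise distance among centroids collapses once c exceeds
the number of real groups, and the c with the largest relative drop
dmin(c)/dmin(c+1) is selected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import Thresholds
from .io import CountMatrix

logger = logging.getLogger(__name__)


@dataclass
class TrajectorySet:
    """z-scored timepoint trajectories keyed by (feature, tissue)."""

    matrix: pd.DataFrame          # MultiIndex (feature_id, tissue) x timepoint
    timepoints: list[float]

    @property
    def keys(self) -> list[tuple[str, str]]:
        return list(self.matrix.index)


@dataclass
class FuzzyClustering:
    c: int
    m: float
    centroids: np.ndarray         # c x timepoints
    memberships: np.ndarray       # keys x c, rows sum to 1
    hard_labels: np.ndarray       # argmax per key
    objective: float
    keys: list[tuple[str, str]] = field(default_factory=list)
    dmin_curve: dict[int, float] = field(default_factory=dict)


def zscore_trajectories(cm: CountMatrix,
                        features: Sequence[str] | None = None,
                        tissues: Sequence[str] | None = None
                        ) -> TrajectorySet:
    """Build z-scored mean-per-timepoint trajectories for each
    (feature, tissue).

    Rows are standardized to mean 0 / unit sample s.d. (ddof=1); constant
    trajectories are dropped (logged).  Fewer than 2 timepoints is an error.
    """
    tissues = list(tissues) if tissues is not None else \
        sorted(cm.samples["tissue"].unique())
    features = list(features) if features is not None else cm.feature_ids
    tps = sorted(cm.samples["age_months"].unique())
    if len(tps) < 2:
        raise ValueError("need at least 2 timepoints to build trajectories")

    blocks = []
    index = []
    for tissue in tissues:
        sub = cm.tissue(tissue)
        ages = sub.samples["age_months"].to_numpy(dtype=float)
        local_tps = sorted(set(ages))
        means = np.column_stack([
            sub.rpmm.loc[features].iloc[:, np.flatnonzero(ages == tp)]
            .mean(axis=1).to_numpy() for tp in local_tps])
        full = np.full((len(features), len(tps)), np.nan)
        for j, tp in enumerate(local_tps):
            full[:, tps.index(tp)] = means[:, j]
        blocks.append(full)
        index.extend((f, tissue) for f in features)
    mat = np.vstack(blocks)

    mu = np.nanmean(mat, axis=1, keepdims=True)
    sd = np.nanstd(mat, axis=1, keepdims=True, ddof=1)
    keep = (sd[:, 0] > 0) & ~np.isnan(sd[:, 0])
    dropped = (~keep).sum()
    if dropped:
        logger.info("dropping %d constant trajectory row(s)", dropped)
    z = (mat[keep] - mu[keep]) / sd[keep]
    df = pd.DataFrame(z, index=pd.MultiIndex.from_tuples(
        [index[i] for i in np.flatnonzero(keep)],
        names=["feature_id", "tissue"]), columns=tps)
    # timepoints missing in some tissue propagate NaN; impute by row mean (0)
    df = df.fillna(0.0)
    return TrajectorySet(matrix=df, timepoints=[float(t) for t in tps])


def _kmeanspp_init(x: np.ndarray, c: int, rng: np.random.Generator
                   ) -> np.ndarray:
    n = x.shape[0]
    centroids = [x[rng.integers(n)]]
    for _ in range(1, c):
        d2 = np.min(((x[:, None, :] - np.asarray(centroids)[None]) ** 2)
                    .sum(-1), axis=1)
        total = d2.sum()
        probs = d2 / total if total > 0 else np.full(n, 1.0 / n)
        centroids.append(x[rng.choice(n, p=probs)])
    return np.asarray(centroids)


def _fcm_once(x: np.ndarray, c: int, m: float, rng: np.random.Generator,
              tol: float, max_iter: int) -> tuple[np.ndarray, np.ndarray,
                                                  float]:
    centroids = _kmeanspp_init(x, c, rng)
    prev_obj = np.inf
    exponent = 2.0 / (m - 1.0)
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centroids[None]) ** 2).sum(-1)
        zero = d2 < 1e-300
        with np.errstate(divide="ignore"):
            inv = d2 ** (-(exponent / 2.0))        # = d^{-2/(m-1)}
        inv = np.where(np.isfinite(inv), inv, 0.0)
        denom = inv.sum(axis=1, keepdims=True)
        u = np.divide(inv, denom, out=np.zeros_like(inv), where=denom > 0)
        # singularity rule: a point on a centroid belongs there entirely
        rows = zero.any(axis=1)
        if rows.any():
            u[rows] = 0.0
            u[rows, np.argmax(zero[rows], axis=1)] = 1.0
        um = u ** m
        obj = float((um * d2).sum())
        if obj > prev_obj + 1e-9 * max(1.0, abs(prev_obj)):
            raise AssertionError("fuzzy c-means objective increased")
        new_centroids = (um.T @ x) / um.sum(axis=0)[:, None]
        shift = np.abs(new_centroids - centroids).max()
        centroids = new_centroids
        if shift < tol:
            prev_obj = obj
            break
        prev_obj = obj
    d2 = ((x[:, None, :] - centroids[None]) ** 2).sum(-1)
    inv = np.where(d2 < 1e-300, np.inf, d2) ** (-(exponent / 2.0))
    finite = np.isfinite(inv)
    u = np.zeros_like(d2)
    singular = ~finite.all(axis=1)
    u[~singular] = inv[~singular] / inv[~singular].sum(axis=1, keepdims=True)
    if singular.any():
        u[singular, np.argmin(d2[singular], axis=1)] = 1.0
    obj = float((u ** m * d2).sum())
    return centroids, u, obj


def fuzzy_cmeans(ts: TrajectorySet, c: int, m: float = 2.0, seed: int = 0,
                 tol: float = 1e-6, max_iter: int = 300, n_init: int = 5
                 ) -> FuzzyClustering:
    """Fuzzy c-means on the trajectory matrix (best of ``n_init`` restarts).

    Standard Bezdek updates: membership u_ik proportional to
    d_ik^(-2/(m-1)), centroid = weighted mean with weights u^m.  The
    objective sum(u^m d^2) is asserted non-increasing every iteration.
    """
    if c < 2:
        raise ValueError("c must be >= 2")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    x = ts.matrix.to_numpy(dtype=float)
    if x.shape[0] < c:
        raise ValueError(f"only {x.shape[0]} trajectories for c={c}")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        centroids, u, obj = _fcm_once(x, c, m, rng, tol, max_iter)
        if best is None or obj < best[2]:
            best = (centroids, u, obj)
    centroids, u, obj = best
    return FuzzyClustering(c=c, m=m, centroids=centroids, memberships=u,
                           hard_labels=np.argmax(u, axis=1), objective=obj,
                           keys=ts.keys)


def min_centroid_distance(centroids: np.ndarray) -> float:
    """Smallest pairwise Euclidean distance among centroids (Dmin)."""
    c = centroids.shape[0]
    dmin = np.inf
    for i in range(c):
        for j in range(i + 1, c):
            dmin = min(dmin, float(np.linalg.norm(centroids[i] -
                                                  centroids[j])))
    return dmin


def select_c(ts: TrajectorySet, c_range: tuple[int, int] = (2, 20),
             m: float = 2.0, seed: int = 0, n_init: int = 3
             ) -> tuple[int, dict[int, float]]:
    """Choose the cluster number from the minimum-centroid-distance curve.

    dmin(c) is computed for each candidate c (best restart by objective);
    the selected c maximizes the relative drop dmin(c)/dmin(c+1).  The full
    curve is returned for inspection.  A c_max exceeding the number of
    trajectories minus one is lowered with a warning.
    """
    c_min, c_max = c_range
    n = ts.matrix.shape[0]
    if c_max >= n:
        warnings.warn(f"c_max {c_max} lowered to {n - 1} (only {n} "
                      "trajectories)")
        c_max = n - 1
    if c_min > c_max:
        raise ValueError("empty c range after adjustment")
    curve: dict[int, float] = {}
    for c in range(c_min, c_max + 2):
        if c > n - 1 and c > c_max:
            break
        fc = fuzzy_cmeans(ts, c, m=m, seed=seed + c, n_init=n_init)
        curve[c] = min_centroid_distance(fc.centroids)
    if c_min == c_max:
        return c_min, {c: curve[c] for c in curve if c <= c_max}
    best_c, best_ratio = c_min, -np.inf
    for c in range(c_min, c_max + 1):
        nxt = curve.get(c + 1)
        if nxt is None or nxt <= 0:
            continue
        ratio = curve[c] / nxt
        if ratio > best_ratio:
            best_c, best_ratio = c, ratio
    return best_c, curve


def tissue_specificity(clustering: FuzzyClustering,
                       th: Thresholds = Thresholds()) -> pd.DataFrame:
    """Per-cluster dominant tissue, its fraction, and the specificity flag.

    A cluster is tissue-specific when at least ``tissue_specific_frac`` of
    its members (hard labels) come from a single tissue; empty clusters are
    excluded.
    """
    tissues = np.array([t for _, t in clustering.keys])
    rows = []
    for k in range(clustering.c):
        members = tissues[clustering.hard_labels == k]
        if len(members) == 0:
            continue
        vals, counts = np.unique(members, return_counts=True)
        i = np.argmax(counts)
        frac = counts[i] / len(members)
        rows.append({"cluster": k, "n_members": len(members),
                     "dominant_tissue": vals[i], "fraction": frac,
                     "is_specific": frac >= th.tissue_specific_frac})
    return pd.DataFrame(rows)
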