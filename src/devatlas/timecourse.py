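"""Soft clustering of developmental expression trajectories.

Genes are summarized as per-stage mean log2(TPM + 0.25) profiles,
row-standardized (z-scores), and clustered by fuzzy c-means: each gene
receives graded memberships over K cluster centroids, with memberships
summing to 1. The number of clusters is chosen by the minimum-centroid-
distance curve — as K grows past the true number of trajectory shapes,
two centroids are forced to split one shape and the minimum pairwise
centroid distance collapses.

Cluster labels are arbitrary: across seeds only the induced partition is
stable, so comparisons use partition metrics (e.g. adjusted Rand), never
label identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import DevAtlasError, ExpressionAtlas
from .qc import log_transform

logger = logging.getLogger(__name__)

__all__ = [
    "FuzzyClustering",
    "stage_profiles",
    "standardize",
    "cmeans",
    "min_centroid_distance",
    "suggest_k",
]


@dataclass
class FuzzyClustering:
    """Result of a fuzzy c-means run.

    ``membership`` is genes x K (rows sum to 1), ``centroids`` is
    K x stages, ``m`` the fuzzification exponent, ``objective`` the final
    weighted within-cluster sum of squares, and ``n_iter`` the sweeps run.
    """

    centroids: np.ndarray
    membership: pd.DataFrame
    m: float
    objective: float
    n_iter: int

    def hard_labels(self) -> pd.Series:
        """Argmax-membership cluster index per gene."""
        return pd.Series(
            np.argmax(self.membership.to_numpy(), axis=1),
            index=self.membership.index,
            name="cluster",
        )


def stage_profiles(atlas: ExpressionAtlas, tissue: str | None = None) -> pd.DataFrame:
    """Per-stage mean of log2(TPM + 0.25), genes x stages in stage order.

    Restricted to one tissue when ``tissue`` is given. Stages with zero
    samples are omitted with a warning.
    """
    sub = atlas.subset_tissue(tissue) if tissue is not None else atlas
    stages = sub.stage_order()
    if len(stages) < 2:
        raise DevAtlasError("need >= 2 stages with samples for stage profiles")
    logmat = log_transform(sub.expression)
    cols = {}
    stage_labels = sub.sample_meta["stage"].astype(str)
    for s in stages:
        mask = (stage_labels == str(s)).to_numpy()
        if not mask.any():
            logger.warning("stage %s has no samples; omitted", s)
            continue
        cols[str(s)] = logmat.to_numpy()[:, mask].mean(axis=1)
    return pd.DataFrame(cols, index=sub.gene_ids)


def standardize(profiles: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-score (population SD); constant rows are dropped.

    The resulting trajectory matrix has every row at mean 0, SD 1, which
    makes Euclidean distance between rows a pure shape comparison.
    """
    if profiles.shape[1] < 2:
        raise DevAtlasError("need >= 2 stages to standardize trajectories")
    vals = profiles.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        logger.info("dropping %d constant trajectory rows", int(constant.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (vals - mu) / sd
    return pd.DataFrame(
        z[~constant], index=profiles.index[~constant], columns=profiles.columns
    )


def _memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """Membership update from squared distances, with the standard
    degenerate rule: a point at distance 0 from a centroid gets full
    membership there."""
    expo = 1.0 / (m - 1.0)
    zero = d2 <= 1e-300
    u = np.empty_like(d2)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d2 ** (-expo)
    ok = ~zero.any(axis=1)
    u[ok] = inv[ok] / inv[ok].sum(axis=1, keepdims=True)
    if (~ok).any():
        u[~ok] = 0.0
        rows = np.where(~ok)[0]
        u[rows, np.argmax(zero[rows], axis=1)] = 1.0
    return u


def cmeans(
    X: pd.DataFrame,
    K: int,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int = 0,
) -> FuzzyClustering:
    """Fuzzy c-means on a standardized trajectory matrix.

    Alternates membership updates
    u_ik = 1 / sum_j (d_ik / d_ij)^(2/(m-1)) and centroid updates
    c_k = sum_i u_ik^m x_i / sum_i u_ik^m until the objective
    J = sum_ik u_ik^m d_ik^2 changes by less than ``tol``. Initial
    centroids are K distinct rows drawn at random (seeded), so runs are
    deterministic given the seed. The objective never increases between
    sweeps (asserted).
    """
    if m <= 1:
        raise DevAtlasError("fuzzification exponent m must be > 1")
    n = X.shape[0]
    if K < 2:
        raise DevAtlasError("K must be >= 2")
    if K > n:
        raise DevAtlasError(f"K={K} exceeds the number of rows {n}")
    rng = np.random.default_rng(seed)
    vals = X.to_numpy(dtype=float)
    centroids = vals[rng.choice(n, size=K, replace=False)].copy()

    prev_obj = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d2 = ((vals[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        u = _memberships(d2, m)
        um = u**m
        w = um.sum(axis=0)
        # a centroid with zero total membership (fully degenerate data)
        # stays where it is instead of dividing by zero
        centroids = np.divide(
            um.T @ vals, w[:, None], out=centroids.copy(), where=w[:, None] > 0
        )
        d2 = ((vals[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        u = _memberships(d2, m)
        obj = float((u**m * d2).sum())
        assert obj <= prev_obj + 1e-9, "c-means objective increased"
        if prev_obj - obj < tol:
            prev_obj = obj
            break
        prev_obj = obj

    membership = pd.DataFrame(
        u, index=X.index, columns=[f"cluster{k + 1}" for k in range(K)]
    )
    return FuzzyClustering(centroids, membership, m, prev_obj, n_iter)


def min_centroid_distance(
    X: pd.DataFrame, K_range, m: float = 2.0, seed: int = 0
) -> pd.Series:
    """Minimum pairwise centroid distance for each K in ``K_range``.

    The standard K-selection diagnostic: the curve drops sharply once K
    exceeds the number of distinct trajectory shapes. The selection
    heuristic (largest K before the first steep drop, see
    :func:`suggest_k`) is reported, not enforced.
    """
    out = {}
    for K in K_range:
        fc = cmeans(X, K, m=m, seed=seed)
        diff = fc.centroids[:, None, :] - fc.centroids[None, :, :]
        d = np.sqrt((diff**2).sum(axis=2))
        iu = np.triu_indices(K, k=1)
        out[K] = float(d[iu].min())
    return pd.Series(out, name="min_centroid_distance").sort_index()


def suggest_k(curve: pd.Series) -> int:
    """K just before the largest drop of the minimum-centroid-distance curve."""
    if len(curve) < 2:
        raise DevAtlasError("need >= 2 K values to suggest K")
    drops = curve.diff().dropna()  # negative values; most negative = biggest drop
    k_after = drops.idxmin()
    ks = list(curve.index)
    return ks[ks.index(k_after) - 1]
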