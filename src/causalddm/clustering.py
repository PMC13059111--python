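"""k-means stratification of questionnaire traits along the ASD-SSD continuum.

The 14 subscale scores (5 AQ + 9 SPQ) are z-scored per column and clustered
with Hartigan–Wong k-means (squared Euclidean distance, at most 25 sweeps,
best of 50 k-means++ restarts).  Solutions over K = 2..10 are scored by mean
silhouette, explained variance R² = 1 − WSS/TSS, and a spherical-Gaussian
BIC; the K with the highest silhouette is selected.  A K = 3 solution is
labeled ASD-like / low-trait (LT) / SSD-like from the centroid z-profiles of
the socio-affective vs cognitive-perceptual subscale groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import kmeans_plusplus
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)

__all__ = [
    "AQ_SUBSCALES", "SPQ_SUBSCALES", "SUBSCALES",
    "ClusterSolution", "zscore_subscales", "kmeans", "score_solution",
    "select_k", "label_clusters",
]

AQ_SUBSCALES = (
    "aq_social_skills", "aq_attention_switching", "aq_attention_to_detail",
    "aq_communication", "aq_imagination",
)
SPQ_SUBSCALES = (
    "spq_ideas_of_reference", "spq_social_anxiety", "spq_odd_beliefs",
    "spq_unusual_perceptual", "spq_odd_behavior", "spq_no_close_friends",
    "spq_odd_speech", "spq_constricted_affect", "spq_suspiciousness",
)
SUBSCALES = AQ_SUBSCALES + SPQ_SUBSCALES

# subscale groups driving the profile labels
COGNITIVE_PERCEPTUAL = (
    "spq_ideas_of_reference", "spq_odd_beliefs", "spq_unusual_perceptual",
    "spq_odd_behavior", "spq_odd_speech", "spq_suspiciousness",
)
SOCIO_AFFECTIVE = (
    "spq_no_close_friends", "spq_social_anxiety", "spq_constricted_affect",
    "aq_social_skills", "aq_communication",
)


@dataclass
class ClusterSolution:
    K: int
    assignments: np.ndarray          # length-n integer cluster indices
    centroids: np.ndarray            # K x d (z-units)
    within_ss: float
    silhouette: float = np.nan
    r2: float = np.nan
    bic: float = np.nan
    labels: dict = field(default_factory=dict)   # cluster index -> profile label
    subject_ids: list = field(default_factory=list)


def zscore_subscales(profiles: pd.DataFrame) -> pd.DataFrame:
    """Z-score each subscale column (sample sd, n−1 denominator).

    Accepts a subjects × subscales table (extra columns such as subject_id
    are carried through untouched if present as the index).  Raises on a
    zero-variance column, naming the subscale.
    """
    cols = [c for c in profiles.columns if c in SUBSCALES]
    if not cols:
        cols = [c for c in profiles.columns if np.issubdtype(profiles[c].dtype, np.number)]
    if len(profiles) < 2:
        raise ValueError("need at least 2 subjects to z-score")
    out = profiles.copy()
    for c in cols:
        sd = profiles[c].std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"subscale '{c}' has zero variance; cannot z-score")
        out[c] = (profiles[c] - profiles[c].mean()) / sd
    return out[cols]


def _within_ss(X, assign, centroids):
    return float(np.sum((X - centroids[assign]) ** 2))


def _hartigan_wong(X: np.ndarray, centers: np.ndarray, max_iter: int = 25):
    """One Hartigan–Wong run from given initial centers.

    Transfer criterion: moving point x from cluster i (size n_i) to j lowers
    the objective iff n_j/(n_j+1)·d(x,c_j)² < n_i/(n_i−1)·d(x,c_i)².  Sweeps
    until no transfer or ``max_iter`` sweeps; the objective is non-increasing
    across sweeps.
    """
    n, d = X.shape
    K = centers.shape[0]
    dist = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    assign = dist.argmin(1)
    counts = np.bincount(assign, minlength=K)
    # recompute centers as means of initial assignment
    centers = np.zeros((K, d))
    for k in range(K):
        if counts[k]:
            centers[k] = X[assign == k].mean(0)
    for _ in range(max_iter):
        moved = False
        for i in range(n):
            ci = assign[i]
            if counts[ci] <= 1:
                continue  # never empty a cluster
            x = X[i]
            d2 = ((centers - x) ** 2).sum(1)
            ni = counts[ci]
            cost_leave = ni / (ni - 1.0) * d2[ci]
            gain = counts / (counts + 1.0) * d2
            gain[ci] = np.inf
            cj = int(gain.argmin())
            if gain[cj] < cost_leave - 1e-12:
                # incremental centroid update
                centers[ci] = (centers[ci] * ni - x) / (ni - 1)
                nj = counts[cj]
                centers[cj] = (centers[cj] * nj + x) / (nj + 1)
                counts[ci] -= 1
                counts[cj] += 1
                assign[i] = cj
                moved = True
        if not moved:
            break
    return assign, centers


def kmeans(X: np.ndarray, K: int, seed: int, n_starts: int = 50,
           max_iter: int = 25) -> ClusterSolution:
    """Hartigan–Wong k-means, best of ``n_starts`` k-means++ restarts."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if K > n:
        raise ValueError(f"K={K} exceeds number of points n={n}")
    if K == 1:
        cent = X.mean(0, keepdims=True)
        return ClusterSolution(K=1, assignments=np.zeros(n, dtype=int),
                               centroids=cent, within_ss=_within_ss(X, np.zeros(n, int), cent))
    rng = np.random.RandomState(seed)
    best = None
    for _ in range(n_starts):
        centers, _ = kmeans_plusplus(X, n_clusters=K, random_state=rng)
        assign, cents = _hartigan_wong(X, centers, max_iter=max_iter)
        wss = _within_ss(X, assign, cents)
        if best is None or wss < best.within_ss - 1e-12:
            best = ClusterSolution(K=K, assignments=assign.copy(),
                                   centroids=cents.copy(), within_ss=wss)
    return best


def score_solution(X: np.ndarray, solution: ClusterSolution) -> ClusterSolution:
    """Attach silhouette, R² and BIC to a solution (in place, also returned).

    Silhouette is the Euclidean mean silhouette; undefined (NaN) at K = 1.
    R² = 1 − WSS/TSS.  BIC uses a spherical-Gaussian mixture approximation
    with pooled variance σ̂² = WSS / (d·(n − K)) and penalty (K·d + K)·ln n.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    tss = float(np.sum((X - X.mean(0)) ** 2))
    solution.r2 = 1.0 - solution.within_ss / tss if tss > 0 else 0.0
    if solution.K >= 2 and len(np.unique(solution.assignments)) >= 2:
        solution.silhouette = float(silhouette_score(X, solution.assignments))
    else:
        solution.silhouette = np.nan
    K = solution.K
    if n > K and solution.within_ss > 0:
        sigma2 = solution.within_ss / (d * (n - K))
        counts = np.bincount(solution.assignments, minlength=K).astype(float)
        ll = (-0.5 * n * d * np.log(2 * np.pi * sigma2)
              - 0.5 * d * (n - K)
              + float(np.sum(counts * np.log(np.maximum(counts, 1) / n))))
        solution.bic = float(-2.0 * ll + (K * d + K) * np.log(n))
    else:
        solution.bic = np.nan
    return solution


def select_k(X: np.ndarray, k_range=range(2, 11), seed: int = 0,
             n_starts: int = 50) -> tuple[ClusterSolution, pd.DataFrame]:
    """Fit and score k-means over ``k_range``; select the max-silhouette K.

    Returns the winning solution and the full score table (one row per K,
    mirroring a cluster-selection summary table).
    """
    X = np.asarray(X, dtype=float)
    rows, solutions = [], {}
    for K in k_range:
        if K > X.shape[0]:
            break
        sol = score_solution(X, kmeans(X, K, seed=seed + K, n_starts=n_starts))
        solutions[K] = sol
        rows.append((K, sol.r2, sol.bic, sol.silhouette, sol.within_ss))
    table = pd.DataFrame(rows, columns=["K", "r2", "bic", "silhouette", "within_ss"])
    best_k = int(table.loc[table["silhouette"].idxmax(), "K"])
    best = solutions[best_k]
    if best.silhouette < 0.3:
        logger.warning("max silhouette %.3f < 0.3: weak cluster structure", best.silhouette)
    return best, table


def label_clusters(solution: ClusterSolution,
                   feature_names=SUBSCALES) -> dict:
    """Assign ASD-like / LT / SSD-like labels to a K = 3 solution.

    The cluster with the highest mean centroid z over the cognitive-perceptual
    SPQ subscales is SSD-like; the highest over the socio-affective subscales
    is ASD-like; the remaining cluster is LT.  Ties (both maxima in one
    cluster) are broken by overall centroid mean — the lowest-mean cluster
    becomes LT, and remaining labels follow the dimension scores.
    """
    if solution.K != 3:
        logger.warning("profile labeling requires K=3 (got K=%d); skipped", solution.K)
        return {}
    names = list(feature_names)
    cp_idx = [names.index(s) for s in COGNITIVE_PERCEPTUAL if s in names]
    sa_idx = [names.index(s) for s in SOCIO_AFFECTIVE if s in names]
    cp = solution.centroids[:, cp_idx].mean(1)
    sa = solution.centroids[:, sa_idx].mean(1)
    ssd = int(np.argmax(cp))
    asd = int(np.argmax(sa))
    if ssd == asd:
        overall = solution.centroids.mean(1)
        lt = int(np.argmin(overall))
        rest = [k for k in range(3) if k != lt]
        # order the remaining two by dimension preference, deterministically
        ssd = rest[0] if cp[rest[0]] - sa[rest[0]] >= cp[rest[1]] - sa[rest[1]] else rest[1]
        asd = [k for k in rest if k != ssd][0]
    lt = [k for k in range(3) if k not in (ssd, asd)][0]
    labels = {asd: "ASD-like", lt: "LT", ssd: "SSD-like"}
    solution.labels = labels
    return labels
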