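"""Hartigan–Wong k-means, scoring, K selection and profile labeling."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from causalddm.clustering import (SUBSCALES, kmeans, label_clusters,
                                  score_solution, select_k, zscore_subscales)


def _exhaustive_best_wss(X, K):
    """Minimal within-SS over all assignments (oracle for tiny n)."""
    n = len(X)
    best = np.inf
    for assign in itertools.product(range(K), repeat=n):
        if len(set(assign)) < K:
            continue
        a = np.array(assign)
        wss = 0.0
        for k in range(K):
            pts = X[a == k]
            wss += ((pts - pts.mean(0)) ** 2).sum()
        best = min(best, wss)
    return best


def test_kmeans_matches_exhaustive_partition_oracle():
    rng = np.random.default_rng(3)
    X = np.vstack([rng.normal(0, 1, (5, 2)), rng.normal(4, 1, (5, 2))])
    sol = kmeans(X, 2, seed=0)
    assert sol.within_ss == pytest.approx(_exhaustive_best_wss(X, 2), rel=1e-9)
    # a harder, less separated configuration
    X2 = rng.normal(0, 1, (10, 2))
    sol2 = kmeans(X2, 2, seed=1)
    assert sol2.within_ss <= _exhaustive_best_wss(X2, 2) + 1e-9


def test_kmeans_k1_and_duplicates():
    X = np.zeros((6, 3))
    sol = kmeans(X + 1.0, 2, seed=0)
    assert sol.within_ss == pytest.approx(0.0)
    rng = np.random.default_rng(0)
    Xr = rng.normal(size=(8, 2))
    s1 = kmeans(Xr, 1, seed=0)
    scored = score_solution(Xr, s1)
    assert scored.r2 == pytest.approx(0.0, abs=1e-12)
    assert np.isnan(scored.silhouette)


def test_kmeans_rejects_k_above_n():
    with pytest.raises(ValueError):
        kmeans(np.zeros((3, 2)), 4, seed=0)


def test_silhouette_matches_hand_computation():
    # two tight triads on a line; silhouette computable by hand
    X = np.array([[0.0], [0.1], [0.2], [10.0], [10.1], [10.2]])
    sol = kmeans(X, 2, seed=0)
    scored = score_solution(X, sol)
    # for point 0: a = (0.1+0.2)/2 = 0.15, b = (10+10.1+10.2)/3 = 10.1
    # by symmetry all points have s ~ (b-a)/b with a=0.15, b in {10.1, 9.8}
    svals = []
    for i in range(6):
        own = [j for j in range(6) if sol.assignments[j] == sol.assignments[i] and j != i]
        other = [j for j in range(6) if sol.assignments[j] != sol.assignments[i]]
        a = np.mean([abs(X[i, 0] - X[j, 0]) for j in own])
        b = np.mean([abs(X[i, 0] - X[j, 0]) for j in other])
        svals.append((b - a) / max(a, b))
    assert scored.silhouette == pytest.approx(np.mean(svals), rel=1e-9)
    assert scored.silhouette > 0.9


def test_select_k_recovers_three_separated_blobs():
    rng = np.random.default_rng(9)
    X = np.vstack([rng.normal(c, 0.5, (20, 4)) for c in (0.0, 5.0, 10.0)])
    best, table = select_k(X, range(2, 6), seed=0, n_starts=20)
    assert best.K == 3
    assert table.loc[table["K"] == 3, "silhouette"].iloc[0] == table["silhouette"].max()
    # r2 non-decreasing in K
    assert (np.diff(table["r2"]) > -1e-9).all()


def test_single_blob_has_weak_silhouette():
    rng = np.random.default_rng(1)
    X = rng.normal(0, 1, (60, 4))
    best, table = select_k(X, range(2, 6), seed=0, n_starts=20)
    assert table["silhouette"].max() < 0.3


def test_zscore_columns_and_errors():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(rng.normal(5, 2, (30, 14)), columns=SUBSCALES)
    z = zscore_subscales(df)
    assert np.allclose(z.mean(0), 0, atol=1e-12)
    assert np.allclose(z.std(0, ddof=1), 1, atol=1e-12)
    df2 = df.copy()
    df2["aq_imagination"] = 3.0
    with pytest.raises(ValueError, match="aq_imagination"):
        zscore_subscales(df2)


def test_label_clusters_from_profile_patterns():
    # centroids: cluster 0 high socio-affective, 1 low, 2 high cog-perceptual
    names = list(SUBSCALES)
    cents = np.zeros((3, 14))
    from causalddm.clustering import COGNITIVE_PERCEPTUAL, SOCIO_AFFECTIVE
    for s in SOCIO_AFFECTIVE:
        cents[0, names.index(s)] = 1.0
    for s in COGNITIVE_PERCEPTUAL:
        cents[2, names.index(s)] = 1.0
    from causalddm.clustering import ClusterSolution
    sol = ClusterSolution(K=3, assignments=np.arange(3), centroids=cents, within_ss=0)
    labels = label_clusters(sol, names)
    assert labels == {0: "ASD-like", 1: "LT", 2: "SSD-like"}
    # all-zero centroids exercise the tie-break path deterministically
    sol0 = ClusterSolution(K=3, assignments=np.arange(3),
                           centroids=np.zeros((3, 14)), within_ss=0)
    labels0 = label_clusters(sol0, names)
    assert sorted(labels0.values()) == ["ASD-like", "LT", "SSD-like"]
    # K != 3 skips with empty result
    sol2 = ClusterSolution(K=2, assignments=np.arange(2),
                           centroids=np.zeros((2, 14)), within_ss=0)
    assert label_clusters(sol2, names) == {}


def test_generated_traits_cluster_recovery(traits_150):
    cfg, traits = traits_150
    X = zscore_subscales(traits.set_index("subject_id"))
    sol = kmeans(X.to_numpy(), 3, seed=2)
    ari = adjusted_rand_score(traits["cluster_truth"], sol.assignments)
    assert ari > 0.8
    labels = label_clusters(score_solution(X.to_numpy(), sol), list(X.columns))
    # majority label within each truth cluster matches the generative identity
    lab = pd.Series([labels[c] for c in sol.assignments], index=traits.index)
    for truth_label in ("ASD-like", "LT", "SSD-like"):
        mask = traits["cluster_truth"] == truth_label
        assert lab[mask].mode().iloc[0] == truth_label
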