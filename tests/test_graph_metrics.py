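"""Graph-metric correctness against exhaustive brute-force oracles.

The oracles enumerate simple paths / triangles directly with plain Python
loops, independent of both the package implementation and networkx.
"""

from itertools import combinations, permutations

import numpy as np
import pytest

from klse.metrics import (
    GLOBAL_METRICS,
    betweenness,
    char_path_length,
    feature_vector,
    global_efficiency,
    global_properties,
    local_clustering,
    local_efficiency,
    modularity,
    node_strength,
    null_networks,
    proportional_threshold,
    regional_properties,
    shortest_path_lengths,
    small_worldness,
    transitivity,
    vulnerability,
)

from conftest import random_weight_matrix


# ---------------------------------------------------------------- oracles


def brute_shortest_paths(W: np.ndarray) -> np.ndarray:
    """All-pairs shortest 1/w-length distance by full path enumeration."""
    n = W.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    nodes = list(range(n))
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            best = np.inf
            inner = [v for v in nodes if v not in (s, t)]
            for k in range(len(inner) + 1):
                for mid in permutations(inner, k):
                    path = (s, *mid, t)
                    length = 0.0
                    ok = True
                    for a, b in zip(path[:-1], path[1:]):
                        if W[a, b] <= 0:
                            ok = False
                            break
                        length += 1.0 / W[a, b]
                    if ok:
                        best = min(best, length)
            D[s, t] = best
    return D


def brute_betweenness(W: np.ndarray) -> np.ndarray:
    """Count of shortest paths through each node (fractional on ties)."""
    n = W.shape[0]
    D = brute_shortest_paths(W)
    bc = np.zeros(n)
    nodes = list(range(n))
    for s, t in combinations(range(n), 2):
        if not np.isfinite(D[s, t]):
            continue
        shortest = []
        inner = [v for v in nodes if v not in (s, t)]
        for k in range(len(inner) + 1):
            for mid in permutations(inner, k):
                path = (s, *mid, t)
                length = 0.0
                ok = True
                for a, b in zip(path[:-1], path[1:]):
                    if W[a, b] <= 0:
                        ok = False
                        break
                    length += 1.0 / W[a, b]
                if ok and np.isclose(length, D[s, t], rtol=1e-12, atol=1e-12):
                    shortest.append(path)
        for path in shortest:
            for v in path[1:-1]:
                bc[v] += 1.0 / len(shortest)
    return bc


def brute_onnela_clustering(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    wmax = W.max()
    What = W / wmax if wmax > 0 else W
    out = np.zeros(n)
    for i in range(n):
        k = int((W[i] > 0).sum())
        if k < 2:
            continue
        tri = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    tri += (What[i, j] * What[i, h] * What[j, h]) ** (1.0 / 3.0)
        out[i] = tri / (k * (k - 1))
    return out


def brute_transitivity(W: np.ndarray) -> float:
    n = W.shape[0]
    wmax = W.max()
    What = W / wmax if wmax > 0 else W
    num = 0.0
    den = 0.0
    for i in range(n):
        k = int((W[i] > 0).sum())
        den += k * (k - 1)
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    num += (What[i, j] * What[i, h] * What[j, h]) ** (1.0 / 3.0)
    return num / den if den > 0 else 0.0


def brute_efficiency(W: np.ndarray) -> float:
    D = brute_shortest_paths(W)
    n = W.shape[0]
    tot = 0.0
    for s in range(n):
        for t in range(n):
            if s != t and np.isfinite(D[s, t]) and D[s, t] > 0:
                tot += 1.0 / D[s, t]
    return tot / (n * (n - 1))


def brute_vulnerability(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    E = brute_efficiency(W)
    out = np.zeros(n)
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        out[i] = (E - brute_efficiency(W[np.ix_(keep, keep)])) / E
    return out


# ---------------------------------------------------------------- tests


@pytest.mark.parametrize("trial", range(25))
def test_oracle_equivalence_random_graphs(trial):
    """Path length, efficiency, betweenness, clustering, transitivity and
    vulnerability all match exhaustive enumeration on random 5-6 node graphs."""
    rng = np.random.default_rng(1000 + trial)
    n = int(rng.integers(5, 7))
    W = random_weight_matrix(rng, n, density=0.8)
    if np.isinf(brute_shortest_paths(W)).any():  # keep connected cases only
        W = random_weight_matrix(rng, n, density=1.0)
    np.testing.assert_allclose(shortest_path_lengths(W), brute_shortest_paths(W), atol=1e-9)
    np.testing.assert_allclose(global_efficiency(W), brute_efficiency(W), atol=1e-9)
    np.testing.assert_allclose(betweenness(W), brute_betweenness(W), atol=1e-9)
    np.testing.assert_allclose(local_clustering(W), brute_onnela_clustering(W), atol=1e-9)
    np.testing.assert_allclose(transitivity(W), brute_transitivity(W), atol=1e-9)
    np.testing.assert_allclose(vulnerability(W), brute_vulnerability(W), atol=1e-9)


def test_hand_computed_path_graph():
    """Unit-weight path A-B-C: d(A,C)=2, efficiency (1+1+0.5)/3, B vulnerability 1."""
    W = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
    D = shortest_path_lengths(W)
    assert D[0, 2] == pytest.approx(2.0)
    assert global_efficiency(W) == pytest.approx((1 + 1 + 0.5) / 3, abs=1e-9)
    v = vulnerability(W)
    assert v[1] == pytest.approx(1.0, abs=1e-9)


def test_unit_triangle_distances():
    W = np.ones((3, 3)) - np.eye(3)
    D = shortest_path_lengths(W)
    off = ~np.eye(3, dtype=bool)
    np.testing.assert_allclose(D[off], 1.0)


def test_star_hub_betweenness():
    """K_{1,3}: all 3 leaf pairs route through the hub."""
    W = np.zeros((4, 4))
    W[0, 1:] = 1.0
    W[1:, 0] = 1.0
    bc = betweenness(W)
    assert bc[0] == pytest.approx(3.0, abs=1e-9)
    np.testing.assert_allclose(bc[1:], 0.0, atol=1e-9)


def test_complete_graph_saturated_metrics():
    """Complete unit-weight graph: efficiency, clustering and transitivity all 1."""
    W = np.ones((6, 6)) - np.eye(6)
    assert global_efficiency(W) == pytest.approx(1.0, abs=1e-9)
    assert local_clustering(W).mean() == pytest.approx(1.0, abs=1e-9)
    assert transitivity(W) == pytest.approx(1.0, abs=1e-9)


def test_two_triangles_modularity():
    """Two disjoint unit triangles: the 2-block partition has Q = 0.5 and
    Louvain finds it (brute-force maximum over all partitions of 6 nodes)."""
    W = np.zeros((6, 6))
    for block in ([0, 1, 2], [3, 4, 5]):
        for a, b in combinations(block, 2):
            W[a, b] = W[b, a] = 1.0
    assert modularity(W, seed=1) == pytest.approx(0.5, abs=1e-9)


def test_node_strength_simple_sum():
    W = np.zeros((3, 3))
    W[0, 1] = W[1, 0] = 0.2
    W[0, 2] = W[2, 0] = 0.3
    assert node_strength(W)[0] == pytest.approx(0.5)


def test_null_networks_preserve_weights_and_determinism():
    rng = np.random.default_rng(5)
    W = random_weight_matrix(rng, 8)
    nulls = null_networks(W, m=5, seed=42)
    iu = np.triu_indices(8, 1)
    for N in nulls:
        np.testing.assert_allclose(np.sort(N[iu]), np.sort(W[iu]))
        assert N.sum() == pytest.approx(W.sum())
        np.testing.assert_allclose(N, N.T)
    again = null_networks(W, m=5, seed=42)
    for a, b in zip(nulls, again):
        np.testing.assert_array_equal(a, b)


def test_small_worldness_of_uniform_graph_is_one():
    """A uniform complete graph equals its own permutation null, so S = 1."""
    W = np.ones((10, 10)) * 0.5
    np.fill_diagonal(W, 0.0)
    assert small_worldness(W, n_null=5, seed=0) == pytest.approx(1.0, abs=1e-12)


def test_weight_scaling_behavior():
    """Scaling weights by c scales strengths by c, distances by 1/c, and
    leaves betweenness rankings unchanged."""
    rng = np.random.default_rng(9)
    W = random_weight_matrix(rng, 7)
    c = 3.7
    np.testing.assert_allclose(node_strength(c * W), c * node_strength(W))
    np.testing.assert_allclose(shortest_path_lengths(c * W), shortest_path_lengths(W) / c)
    np.testing.assert_array_equal(
        np.argsort(betweenness(c * W)), np.argsort(betweenness(W))
    )


def test_feature_vector_shape_and_names():
    """R regions give exactly 7 + 5R uniquely named features."""
    rng = np.random.default_rng(3)
    W = random_weight_matrix(rng, 8)
    fv = feature_vector(W, seed=0, n_null=5)
    assert len(fv) == 7 + 5 * 8
    assert not fv.index.has_duplicates
    assert list(fv.index[:7]) == list(GLOBAL_METRICS)
    assert np.isfinite(fv.to_numpy()).all()


def test_feature_vector_region_permutation_equivariance():
    """Permuting regions permutes regional entries and fixes global ones."""
    rng = np.random.default_rng(4)
    W = random_weight_matrix(rng, 8)
    perm = rng.permutation(8)
    Wp = W[np.ix_(perm, perm)]
    for metric in ("degree", "local_clustering", "vulnerability"):
        a = regional_properties(W)[metric]
        b = regional_properties(Wp)[metric]
        np.testing.assert_allclose(b, a[perm], atol=1e-9)
    ga = global_properties(W, n_null=1)
    gb = global_properties(Wp, n_null=1)
    for m in ("global_efficiency", "transitivity", "char_path_length", "clustering_coefficient"):
        assert ga[m] == pytest.approx(gb[m], abs=1e-9)


def test_proportional_threshold_keeps_strongest_edges():
    rng = np.random.default_rng(11)
    W = random_weight_matrix(rng, 10)
    Wt = proportional_threshold(W, 0.3)
    iu = np.triu_indices(10, 1)
    kept = (Wt[iu] > 0).sum()
    assert kept == int(np.ceil(0.3 * iu[0].size))
    assert set(Wt[iu][Wt[iu] > 0]) <= set(W[iu])


def test_isolated_node_local_metrics_zero():
    W = np.zeros((4, 4))
    W[0, 1] = W[1, 0] = 1.0
    assert local_efficiency(W)[3] == 0.0
    assert local_clustering(W)[3] == 0.0
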