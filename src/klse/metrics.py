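"""Weighted graph metrics for metabolic networks.

Seven global properties (mean Onnela clustering, characteristic path length,
small-worldness, global efficiency, transitivity, strength assortativity,
Louvain modularity) and five regional properties per node (strength degree,
betweenness centrality, local efficiency, vulnerability, local clustering),
giving 7 + 5R features — 457 for the 90-region atlas.

Conventions follow the Brain Connectivity Toolbox's weighted definitions:
edge length = 1/weight for path-based metrics; Onnela geometric-mean
clustering on weights normalized by the maximum; vulnerability is the
relative drop in global efficiency when a node is deleted. Networks are
analysed fully weighted with no thresholding by default; an optional
proportional threshold is available for sensitivity analyses.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_sp

from .network import ConnectivityMatrix

__all__ = [
    "GLOBAL_METRICS",
    "REGIONAL_METRICS",
    "shortest_path_lengths",
    "global_properties",
    "regional_properties",
    "null_networks",
    "feature_vector",
    "proportional_threshold",
]

GLOBAL_METRICS = (
    "clustering_coefficient",
    "char_path_length",
    "small_worldness",
    "global_efficiency",
    "transitivity",
    "assortativity",
    "modularity",
)
REGIONAL_METRICS = ("betweenness", "degree", "local_efficiency", "vulnerability", "local_clustering")


def _as_weights(net) -> np.ndarray:
    W = net.weights if isinstance(net, ConnectivityMatrix) else np.asarray(net, dtype=np.float64)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("need a square weight matrix")
    if np.any(W < 0):
        raise ValueError("weights must be nonnegative")
    W = (W + W.T) / 2.0
    W = W.copy()
    np.fill_diagonal(W, 0.0)
    return W


def shortest_path_lengths(net) -> np.ndarray:
    """All-pairs shortest-path distances with edge length 1/weight.

    Zero-weight (absent) edges have infinite length; unreachable pairs get
    an infinite distance.
    """
    W = _as_weights(net)
    with np.errstate(divide="ignore"):
        L = np.where(W > 0, 1.0 / W, 0.0)
    D = _csgraph_sp(csr_matrix(L), method="D", directed=False)
    np.fill_diagonal(D, 0.0)
    return D


def _efficiency_from_dist(D: np.ndarray) -> float:
    R = D.shape[0]
    if R < 2:
        return 0.0
    off = ~np.eye(R, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(D[off] > 0, 1.0 / D[off], 0.0)
    inv[~np.isfinite(D[off])] = 0.0
    return float(inv.mean())


def global_efficiency(net) -> float:
    """Mean inverse shortest-path distance over all node pairs."""
    return _efficiency_from_dist(shortest_path_lengths(net))


def _onnela_terms(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-node geometric-mean triangle intensity and degree-pair count."""
    wmax = W.max()
    What = W / wmax if wmax > 0 else W
    C3 = np.linalg.matrix_power(np.cbrt(What), 3)
    tri = np.diag(C3)  # sum over (j,h) of (w_ij w_ih w_jh)^(1/3)
    k = (W > 0).sum(axis=1)
    pairs = k * (k - 1)
    return tri, pairs.astype(float)


def local_clustering(net) -> np.ndarray:
    """Onnela weighted clustering coefficient per node (0 when degree < 2)."""
    W = _as_weights(net)
    tri, pairs = _onnela_terms(W)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(pairs > 0, tri / pairs, 0.0)
    return c


def transitivity(net) -> float:
    """Weighted transitivity: total triangle intensity over total degree pairs."""
    W = _as_weights(net)
    tri, pairs = _onnela_terms(W)
    denom = pairs.sum()
    return float(tri.sum() / denom) if denom > 0 else 0.0


def strength_assortativity(net) -> float:
    """Pearson correlation of endpoint strengths over edges (both orientations).

    Returns 0 for degenerate (constant-strength) networks such as uniform
    complete graphs, where the correlation is undefined.
    """
    W = _as_weights(net)
    s = W.sum(axis=1)
    iu, ju = np.nonzero(np.triu(W, k=1))
    if iu.size < 2:
        return 0.0
    x = np.concatenate([s[iu], s[ju]])
    y = np.concatenate([s[ju], s[iu]])
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def _to_graph(W: np.ndarray) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(range(W.shape[0]))
    iu, ju = np.nonzero(np.triu(W, k=1))
    for i, j in zip(iu.tolist(), ju.tolist()):
        G.add_edge(i, j, weight=float(W[i, j]), distance=1.0 / float(W[i, j]))
    return G


def modularity(net, seed: int = 0, n_restarts: int = 10, resolution: float = 1.0) -> float:
    """Best Louvain modularity over seeded restarts (weighted, resolution 1)."""
    W = _as_weights(net)
    G = _to_graph(W)
    if G.number_of_edges() == 0:
        return 0.0
    best = -np.inf
    for k in range(n_restarts):
        parts = nx.community.louvain_communities(G, weight="weight", resolution=resolution, seed=seed + k)
        q = nx.community.modularity(G, parts, weight="weight", resolution=resolution)
        best = max(best, q)
    return float(best)


def betweenness(net) -> np.ndarray:
    """Unnormalized weighted betweenness centrality on 1/weight edge lengths."""
    W = _as_weights(net)
    G = _to_graph(W)
    bc = nx.betweenness_centrality(G, weight="distance", normalized=False)
    return np.array([bc[i] for i in range(W.shape[0])])


def node_strength(net) -> np.ndarray:
    """Weighted degree: sum of incident edge weights."""
    return _as_weights(net).sum(axis=1)


def local_efficiency(net) -> np.ndarray:
    """Global efficiency of each node's neighborhood subgraph (0 if < 2 neighbors)."""
    W = _as_weights(net)
    R = W.shape[0]
    out = np.zeros(R)
    for i in range(R):
        nbrs = np.nonzero(W[i] > 0)[0]
        if nbrs.size < 2:
            continue
        sub = W[np.ix_(nbrs, nbrs)]
        out[i] = _efficiency_from_dist(shortest_path_lengths(sub))
    return out


def vulnerability(net) -> np.ndarray:
    """Relative global-efficiency drop on single-node deletion.

    V_i = (E - E_{-i}) / E with intact efficiency E; 0 everywhere if E = 0.
    Positive values mark nodes whose loss degrades network integration.
    """
    W = _as_weights(net)
    R = W.shape[0]
    E = global_efficiency(W)
    if E == 0:
        return np.zeros(R)
    out = np.empty(R)
    idx = np.arange(R)
    for i in range(R):
        keep = idx[idx != i]
        out[i] = (E - global_efficiency(W[np.ix_(keep, keep)])) / E
    return out


def char_path_length(net) -> float:
    """Mean shortest-path distance over finite off-diagonal pairs."""
    D = shortest_path_lengths(net)
    R = D.shape[0]
    off = ~np.eye(R, dtype=bool)
    vals = D[off]
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        return np.inf
    return float(finite.mean())


def null_networks(net, m: int = 20, seed: int = 0) -> list[np.ndarray]:
    """Topology-destroying nulls: random permutations of upper-triangle weights.

    Preserves the edge-weight multiset (hence total strength) exactly.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    W = _as_weights(net)
    R = W.shape[0]
    iu = np.triu_indices(R, k=1)
    vals = W[iu]
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(m):
        perm = rng.permutation(vals)
        N = np.zeros_like(W)
        N[iu] = perm
        N = N + N.T
        out.append(N)
    return out


def small_worldness(net, n_null: int = 20, seed: int = 0) -> float:
    """S = (C/C_null) / (L/L_null) against weight-permutation nulls."""
    W = _as_weights(net)
    C = float(local_clustering(W).mean())
    L = char_path_length(W)
    nulls = null_networks(W, m=n_null, seed=seed)
    C0 = float(np.mean([local_clustering(N).mean() for N in nulls]))
    L0 = float(np.mean([char_path_length(N) for N in nulls]))
    if C0 == 0 or L0 == 0 or not np.isfinite(L) or L == 0:
        return np.nan
    return float((C / C0) / (L / L0))


def global_properties(net, seed: int = 0, n_null: int = 20) -> dict[str, float]:
    """The seven global network properties as a name -> value mapping."""
    W = _as_weights(net)
    return {
        "clustering_coefficient": float(local_clustering(W).mean()),
        "char_path_length": char_path_length(W),
        "small_worldness": small_worldness(W, n_null=n_null, seed=seed),
        "global_efficiency": global_efficiency(W),
        "transitivity": transitivity(W),
        "assortativity": strength_assortativity(W),
        "modularity": modularity(W, seed=seed),
    }


def regional_properties(net) -> dict[str, np.ndarray]:
    """The five regional property vectors as a name -> length-R array mapping."""
    W = _as_weights(net)
    return {
        "betweenness": betweenness(W),
        "degree": node_strength(W),
        "local_efficiency": local_efficiency(W),
        "vulnerability": vulnerability(W),
        "local_clustering": local_clustering(W),
    }


def proportional_threshold(net, density: float) -> np.ndarray:
    """Keep the strongest ``density`` fraction of unique edges, zero the rest."""
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    W = _as_weights(net)
    iu = np.triu_indices(W.shape[0], k=1)
    vals = W[iu]
    k = int(np.ceil(density * vals.size))
    cut = np.sort(vals)[-k]
    out = np.where(W >= cut, W, 0.0)
    np.fill_diagonal(out, 0.0)
    return out


def feature_vector(net, seed: int = 0, n_null: int = 20):
    """All 7 + 5R properties as a named pandas Series (457 at R = 90).

    Regional entries are named ``metric__region`` using the network's region
    labels; ordering is the seven global metrics followed by regional metrics
    grouped by metric then region. Any non-finite value raises, naming the
    metric.
    """
    import pandas as pd

    labels = (
        net.region_labels
        if isinstance(net, ConnectivityMatrix)
        else [f"region_{i + 1:02d}" for i in range(np.asarray(net).shape[0])]
    )
    g = global_properties(net, seed=seed, n_null=n_null)
    r = regional_properties(net)
    names: list[str] = list(GLOBAL_METRICS)
    values: list[float] = [g[m] for m in GLOBAL_METRICS]
    for metric in REGIONAL_METRICS:
        for j, lab in enumerate(labels):
            names.append(f"{metric}__{lab}")
            values.append(float(r[metric][j]))
    s = pd.Series(values, index=names, dtype=float)
    if s.index.has_duplicates:
        raise ValueError("duplicate feature names")
    bad = s.index[~np.isfinite(s.to_numpy())]
    if len(bad):
        raise ValueError(f"non-finite metrics: {list(bad)}")
    return s
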