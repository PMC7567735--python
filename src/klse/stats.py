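"""Validation statistics for individual metabolic networks.

Three analyses: (1) edge-wise group difference patterns — Fisher-Z transform
the weights, Welch t-test each unique edge, Benjamini-Hochberg FDR across the
R(R-1)/2 edges, and summarize significant edges per lobe; (2) network
stability — the mean Spearman correlation between the vectorized networks of
every subject pair; (3) regional inter-individual dissimilarity — for each
region, the mean over subject pairs of one minus the Spearman correlation of
that region's connectivity profile, Z-normalized across regions and
aggregated by lobe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .network import ConnectivityMatrix

__all__ = [
    "DifferencePattern",
    "SimilarityResult",
    "DissimilarityMap",
    "LobeAlteration",
    "fisher_z",
    "edgewise_difference_pattern",
    "lobe_alteration_fraction",
    "inter_subject_similarity",
    "regional_dissimilarity",
    "lobe_mean_z",
]

_CLIP = 1.0 - 1e-7


def fisher_z(matrix: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Elementwise Fisher Z (atanh) of off-diagonal weights, clipped at +/-(1-1e-7)."""
    W = matrix.weights if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix, float)
    Z = np.arctanh(np.clip(W, -_CLIP, _CLIP))
    np.fill_diagonal(Z, 0.0)
    return Z


@dataclass
class DifferencePattern:
    """Edge-wise two-group comparison with BH-FDR across unique edges."""

    t_stat: np.ndarray
    p_value: np.ndarray
    q_value: np.ndarray
    significant: np.ndarray
    alpha: float
    region_labels: list[str] = field(default_factory=list)

    @property
    def n_regions(self) -> int:
        return self.t_stat.shape[0]

    def significant_edges(self) -> list[tuple[int, int]]:
        """Unique significant edges as (i, j) index pairs, i < j."""
        iu, ju = np.triu_indices(self.n_regions, k=1)
        keep = self.significant[iu, ju]
        return list(zip(iu[keep].tolist(), ju[keep].tolist()))


def _stack_upper(nets: list[ConnectivityMatrix]) -> tuple[np.ndarray, int]:
    R = nets[0].n_regions
    for m in nets:
        if m.n_regions != R:
            raise ValueError("networks differ in size")
    iu = np.triu_indices(R, k=1)
    return np.stack([fisher_z(m)[iu] for m in nets]), R


def edgewise_difference_pattern(
    nets_a: list[ConnectivityMatrix],
    nets_b: list[ConnectivityMatrix],
    alpha: float = 0.05,
    equal_var: bool = False,
) -> DifferencePattern:
    """Welch (default) two-sample t per edge on Fisher-Z weights, BH-FDR corrected.

    Significance is q < alpha over the R(R-1)/2 unique upper-triangle edges;
    edges with zero variance in both groups get t = 0, p = 1 with a warning.
    """
    if len(nets_a) < 2 or len(nets_b) < 2:
        raise ValueError("need >= 2 networks per group")
    A, R = _stack_upper(nets_a)
    B, _ = _stack_upper(nets_b)
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups have different network sizes")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(A, B, axis=0, equal_var=equal_var)
    dead = (A.std(axis=0) == 0) & (B.std(axis=0) == 0)
    if dead.any():
        warnings.warn(f"{int(dead.sum())} edges with zero variance in both groups: p set to 1")
    t = np.where(np.isfinite(t), t, 0.0)
    p = np.where(np.isfinite(p), p, 1.0)
    t[dead] = 0.0
    p[dead] = 1.0
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    sig = q < alpha

    iu = np.triu_indices(R, k=1)

    def to_mat(v, fill=0.0):
        M = np.full((R, R), fill)
        M[iu] = v
        M[(iu[1], iu[0])] = v
        np.fill_diagonal(M, 0.0 if fill == 0.0 else fill)
        return M

    T = to_mat(t)
    P = to_mat(p, fill=1.0)
    Q = to_mat(q, fill=1.0)
    S = to_mat(sig.astype(float)).astype(bool)
    np.fill_diagonal(S, False)
    return DifferencePattern(
        t_stat=T, p_value=P, q_value=Q, significant=S, alpha=alpha,
        region_labels=list(nets_a[0].region_labels),
    )


@dataclass
class LobeAlteration:
    """Per-lobe share of significant edges; ``empty`` flags a null pattern."""

    fractions: dict[str, float]
    total_significant: int
    mode: str

    @property
    def empty(self) -> bool:
        return self.total_significant == 0


def lobe_alteration_fraction(
    pattern: DifferencePattern,
    lobe_of: dict[int, str],
    mode: str = "touch",
) -> LobeAlteration:
    """Fraction of significant unique edges attributed to each lobe.

    ``lobe_of`` maps 1-based region labels to lobe names and must cover all
    regions. ``mode="touch"`` counts an edge for a lobe when at least one
    endpoint lies in it (so fractions over lobes need not sum to 1);
    ``mode="within"`` requires both endpoints. The denominator is the total
    number of significant unique edges.
    """
    if mode not in ("touch", "within"):
        raise ValueError("mode must be 'touch' or 'within'")
    R = pattern.n_regions
    missing = [i for i in range(1, R + 1) if i not in lobe_of]
    if missing:
        raise ValueError(f"lobe_of missing regions {missing}")
    edges = pattern.significant_edges()
    lobes = sorted(set(lobe_of.values()))
    counts = {lb: 0 for lb in lobes}
    for i, j in edges:
        li, lj = lobe_of[i + 1], lobe_of[j + 1]
        if mode == "touch":
            for lb in {li, lj}:
                counts[lb] += 1
        else:
            if li == lj:
                counts[li] += 1
    total = len(edges)
    if total == 0:
        warnings.warn("no significant edges; all lobe fractions are 0")
        return LobeAlteration({lb: 0.0 for lb in lobes}, 0, mode)
    return LobeAlteration({lb: counts[lb] / total for lb in lobes}, total, mode)


@dataclass
class SimilarityResult:
    """Mean pairwise Spearman similarity between whole networks."""

    R_bar: float
    pair_correlations: np.ndarray


def _rank_rows(X: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(sps.rankdata, 1, X)


def _pairwise_spearman(X: np.ndarray) -> np.ndarray:
    """Spearman correlation of every unordered row pair of X (m, k)."""
    ranks = _rank_rows(X)
    sd = ranks.std(axis=1)
    const = sd == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant vectors: their pair correlations set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(ranks)
    C[~np.isfinite(C)] = 0.0
    C[const, :] = 0.0
    C[:, const] = 0.0
    iu = np.triu_indices(X.shape[0], k=1)
    return C[iu]


def inter_subject_similarity(networks: list[ConnectivityMatrix]) -> SimilarityResult:
    """Mean Spearman correlation between the vectorized networks of all pairs.

    Each network is reduced to its R(R-1)/2 unique edge weights; every
    unordered subject pair contributes one rank correlation (average ranks on
    ties) and R_bar is their mean — m(m-1)/2 pair correlations for m subjects.
    """
    if len(networks) < 2:
        raise ValueError("need >= 2 networks")
    X = np.stack([m.upper_values() for m in networks])
    pc = _pairwise_spearman(X)
    return SimilarityResult(R_bar=float(pc.mean()), pair_correlations=pc)


@dataclass
class DissimilarityMap:
    """Regional inter-individual dissimilarity V, its Z-map, and lobe means."""

    V: np.ndarray
    z: np.ndarray
    lobe_means: dict[str, float] = field(default_factory=dict)


def regional_dissimilarity(
    networks: list[ConnectivityMatrix],
    lobe_of: dict[int, str] | None = None,
) -> DissimilarityMap:
    """Per-region mean (1 - Spearman) of connectivity profiles across subject pairs.

    Region i's profile in a subject is row i of the network with the
    self-entry removed (the stored diagonal is a convention, not data).
    V_i averages 1 - rho over all unordered subject pairs, so V_i lies in
    [0, 2] and is 0 when all subjects share identical profiles. The Z-map
    standardizes V across regions (population SD); a constant V yields an
    all-zero Z-map.
    """
    if len(networks) < 2:
        raise ValueError("need >= 2 networks")
    m = len(networks)
    R = networks[0].n_regions
    V = np.empty(R)
    for i in range(R):
        rows = np.stack([np.delete(net.weights[i], i) for net in networks])
        pc = _pairwise_spearman(rows)
        V[i] = float(np.mean(1.0 - pc))
    mu, sd = V.mean(), V.std()
    z = (V - mu) / sd if sd > 0 else np.zeros_like(V)
    lobe_means = {}
    if lobe_of is not None:
        for lb in sorted(set(lobe_of.values())):
            idx = [i for i in range(R) if lobe_of[i + 1] == lb]
            lobe_means[lb] = float(z[idx].mean())
    return DissimilarityMap(V=V, z=z, lobe_means=lobe_means)


def lobe_mean_z(
    dmap: DissimilarityMap,
    lobe_of: dict[int, str],
) -> tuple[dict[str, float], dict[tuple[str, str], float]]:
    """Mean Z-dissimilarity per lobe plus Welch t-tests between lobe pairs.

    Lobes with fewer than 2 regions get a mean but no tests. Two constant,
    equal groups compare with p = 1.
    """
    R = dmap.z.size
    groups: dict[str, np.ndarray] = {}
    for lb in sorted(set(lobe_of.values())):
        idx = [i for i in range(R) if lobe_of.get(i + 1) == lb]
        if idx:
            groups[lb] = dmap.z[idx]
    means = {lb: float(v.mean()) for lb, v in groups.items()}
    pvals: dict[tuple[str, str], float] = {}
    labels = list(groups)
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            x, y = groups[labels[a]], groups[labels[b]]
            if x.size < 2 or y.size < 2:
                continue
            if x.std() == 0 and y.std() == 0:
                p = 1.0 if x.mean() == y.mean() else 0.0
            else:
                with np.errstate(invalid="ignore", divide="ignore"):
                    _, p = sps.ttest_ind(x, y, equal_var=False)
                if not np.isfinite(p):
                    p = 1.0
            pvals[(labels[a], labels[b])] = float(p)
    return means, pvals
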