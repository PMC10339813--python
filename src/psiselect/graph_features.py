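"""Fourteen scalar topology features of a binary undirected network.

The fixed feature order — DG, NB, CC, SPL, EB, GE, LE, TT, AC, SW, MD, MZ,
HC, GIC — is the contract used by feature tables and by the bit layout of
the feature-selection particles, so it must never change.

Node- and edge-level metrics are reduced to one scalar per network by an
unweighted arithmetic mean (raw, unnormalized betweenness; shortest paths
averaged over reachable pairs only).  Every degenerate case (edgeless
graphs, zero-variance degrees, empty null ensembles ...) maps to 0 with a
logged warning rather than NaN, so every epoch yields a classifier-ready
finite vector.

The two null-model features (small-worldness SW and triangle-motif z-score
MZ) are normalized against a Maslov–Sneppen degree-preserving rewired
ensemble and are the only stochastic entries; they are reproducible given
the ensemble seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import networkx as nx

from .connectivity import BinaryNetwork

__all__ = [
    "FEATURE_NAMES",
    "NullEnsembleSpec",
    "degree_mean",
    "betweenness",
    "clustering_transitivity",
    "path_metrics",
    "local_efficiency",
    "assortativity",
    "small_worldness",
    "modularity",
    "motif_zscore",
    "hierarchy_coefficient",
    "graph_index_complexity",
    "feature_vector",
]

logger = logging.getLogger(__name__)

#: Canonical order of the 14 features.
FEATURE_NAMES: tuple[str, ...] = (
    "DG", "NB", "CC", "SPL", "EB", "GE", "LE",
    "TT", "AC", "SW", "MD", "MZ", "HC", "GIC",
)


@dataclass(frozen=True)
class NullEnsembleSpec:
    """Degree-preserving rewired null ensemble for SW and MZ."""

    n_random: int = 100
    rewires_per_edge: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_random < 1:
            raise ValueError("n_random must be >= 1")
        if self.rewires_per_edge < 1:
            raise ValueError("rewires_per_edge must be >= 1")


def _graph(net: BinaryNetwork | nx.Graph | np.ndarray) -> nx.Graph:
    if isinstance(net, nx.Graph):
        return net
    if isinstance(net, BinaryNetwork):
        return nx.from_numpy_array(net.adjacency)
    return nx.from_numpy_array(np.asarray(net))


def degree_mean(net) -> float:
    """DG: mean node degree."""
    g = _graph(net)
    if g.number_of_nodes() == 0:
        return 0.0
    return float(np.mean([d for _, d in g.degree()]))


def betweenness(net) -> tuple[float, float]:
    """(NB, EB): mean raw node and edge betweenness.

    Raw convention: each unordered pair contributes the fraction of its
    shortest paths through the node/edge, with no normalization by the pair
    count.  Unreachable pairs contribute nothing.  An edgeless graph has
    EB = 0 by definition.
    """
    g = _graph(net)
    nb = float(np.mean(list(nx.betweenness_centrality(g, normalized=False).values())))
    if g.number_of_edges() == 0:
        return nb, 0.0
    eb = float(np.mean(list(
        nx.edge_betweenness_centrality(g, normalized=False).values()
    )))
    return nb, eb


def clustering_transitivity(net) -> tuple[float, float]:
    """(CC, TT): mean local clustering (degree-<2 nodes count 0) and global
    transitivity 3*triangles/triples."""
    g = _graph(net)
    if g.number_of_nodes() == 0:
        return 0.0, 0.0
    return float(nx.average_clustering(g)), float(nx.transitivity(g))


def _mean_shortest_path_reachable(g: nx.Graph) -> float:
    """Mean geodesic length over reachable ordered pairs (i != j); 0 if none."""
    total = 0.0
    count = 0
    for _, dists in nx.all_pairs_shortest_path_length(g):
        for d in dists.values():
            if d > 0:
                total += d
                count += 1
    if count == 0:
        logger.warning("no reachable node pair; SPL set to 0")
        return 0.0
    return total / count


def path_metrics(net) -> tuple[float, float]:
    """(SPL, GE): mean shortest path over reachable pairs, and global
    efficiency (mean 1/d over all ordered pairs, 1/inf = 0)."""
    g = _graph(net)
    if g.number_of_nodes() < 2:
        return 0.0, 0.0
    return _mean_shortest_path_reachable(g), float(nx.global_efficiency(g))


def local_efficiency(net) -> float:
    """LE: mean over nodes of the global efficiency of the neighbour-induced
    subgraph; nodes with fewer than two neighbours contribute 0."""
    g = _graph(net)
    if g.number_of_nodes() == 0:
        return 0.0
    return float(nx.local_efficiency(g))


def assortativity(net) -> float:
    """AC: Pearson correlation of degrees across edge endpoints (both
    orientations).  Degree-regular graphs have zero variance at the edge
    ends; that degenerate case returns 0."""
    g = _graph(net)
    if g.number_of_edges() == 0:
        logger.warning("assortativity of an edgeless graph set to 0")
        return 0.0
    degs = dict(g.degree())
    ends = np.array([(degs[u], degs[v]) for u, v in g.edges()], dtype=float)
    xs = np.concatenate([ends[:, 0], ends[:, 1]])
    ys = np.concatenate([ends[:, 1], ends[:, 0]])
    if np.ptp(xs) == 0.0 or np.ptp(ys) == 0.0:
        logger.warning("degree-regular graph: assortativity undefined, set to 0")
        return 0.0
    return float(np.corrcoef(xs, ys)[0, 1])


def _rewire_degree_preserving(
    adj: np.ndarray, rewires_per_edge: int, rng: np.random.Generator
) -> np.ndarray:
    """One Maslov-Sneppen randomization: repeated double edge swaps
    (u-v, x-y) -> (u-y, x-v), each of which preserves every node degree.

    Dense graphs admit few (for the complete graph, zero) valid swaps, so
    the attempt loop bails out after a run of consecutive failures instead
    of burning a large fixed try budget.
    """
    a = adj.copy()
    edges = np.argwhere(np.triu(a, 1))
    m = len(edges)
    if m < 2:
        return a
    target = rewires_per_edge * m
    swaps = 0
    failures = 0
    max_consecutive_failures = 200
    edges = [tuple(e) for e in edges.tolist()]
    batch = max(256, 2 * target)
    pool_i = iter(())
    pool_f = iter(())
    while swaps < target and failures < max_consecutive_failures:
        try:
            e1 = next(pool_i)
            e2 = next(pool_i)
            flip = next(pool_f)
        except StopIteration:
            pool_i = iter(rng.integers(0, m, size=2 * batch).tolist())
            pool_f = iter((rng.random(batch) < 0.5).tolist())
            continue
        if e1 == e2:
            failures += 1
            continue
        u, v = edges[e1]
        x, y = edges[e2]
        if flip:
            x, y = y, x
        if len({u, v, x, y}) < 4 or a[u, y] or a[x, v]:
            failures += 1
            continue
        a[u, v] = a[v, u] = 0
        a[x, y] = a[y, x] = 0
        a[u, y] = a[y, u] = 1
        a[x, v] = a[v, x] = 1
        edges[e1] = (u, y)
        edges[e2] = (x, v)
        swaps += 1
        failures = 0
    return a


def _clustering_spl_triangles(a: np.ndarray) -> tuple[float, float, int]:
    """(mean local clustering, reachable-pairs mean geodesic, triangle count)
    of an adjacency matrix, via matrix powers and a sparse BFS."""
    from scipy.sparse.csgraph import shortest_path

    a = a.astype(float)
    k = a.sum(axis=1)
    tri_per_node = np.diag(a @ a @ a) / 2.0
    denom = k * (k - 1.0)
    local = np.divide(
        2.0 * tri_per_node, denom, out=np.zeros_like(denom), where=denom > 0
    )
    cc = float(local.mean()) if a.shape[0] else 0.0
    d = shortest_path(a, method="D", unweighted=True)
    finite = np.isfinite(d) & (d > 0)
    spl = float(d[finite].mean()) if finite.any() else 0.0
    return cc, spl, int(round(tri_per_node.sum() / 3.0))


def _null_ensemble_stats(
    adj: np.ndarray, ens: NullEnsembleSpec
) -> tuple[float, float, float, float]:
    """(mean CC, mean SPL, mean triangles, sd triangles) over the rewired
    null ensemble, deterministic given ``ens.seed``."""
    rng = np.random.default_rng(ens.seed)
    ccs, spls, tris = [], [], []
    for _ in range(ens.n_random):
        a = _rewire_degree_preserving(adj, ens.rewires_per_edge, rng)
        cc, spl, t = _clustering_spl_triangles(a)
        ccs.append(cc)
        spls.append(spl)
        tris.append(t)
    tris = np.asarray(tris, dtype=float)
    return float(np.mean(ccs)), float(np.mean(spls)), float(tris.mean()), float(tris.std(ddof=0))


def small_worldness(net, ens: NullEnsembleSpec = NullEnsembleSpec()) -> float:
    """SW: sigma = (CC / CC_rand) / (SPL / SPL_rand) against the rewired
    ensemble.  sigma > 1 marks small-world organization (high clustering at
    short path length).  Returns 0 when the null means vanish."""
    g = _graph(net)
    if g.number_of_edges() == 0:
        logger.warning("small-worldness of an edgeless graph set to 0")
        return 0.0
    adj = nx.to_numpy_array(g, dtype=int)
    cc, spl, _ = _clustering_spl_triangles(adj)
    cc_rand, spl_rand, _, _ = _null_ensemble_stats(adj, ens)
    if cc_rand == 0.0 or spl_rand == 0.0 or spl == 0.0:
        logger.warning("degenerate null ensemble: small-worldness set to 0")
        return 0.0
    return float((cc / cc_rand) / (spl / spl_rand))


def modularity(net) -> float:
    """MD: Newman modularity Q of a greedy agglomerative partition.

    Greedy modularity maximization is deterministic here (ties resolved by
    community index order inside networkx's CNM implementation)."""
    g = _graph(net)
    if g.number_of_edges() == 0:
        logger.warning("modularity of an edgeless graph set to 0")
        return 0.0
    communities = nx.community.greedy_modularity_communities(g)
    return float(nx.community.modularity(g, communities))


def motif_zscore(net, ens: NullEnsembleSpec = NullEnsembleSpec()) -> float:
    """MZ: z-score of the triangle (3-cycle motif) count against the rewired
    ensemble: (T - mean T_rand) / sd(T_rand); 0 when the null sd vanishes."""
    g = _graph(net)
    if g.number_of_nodes() < 3:
        return 0.0
    adj = nx.to_numpy_array(g, dtype=int)
    _, _, t_real = _clustering_spl_triangles(adj)
    _, _, t_mean, t_sd = _null_ensemble_stats(adj, ens)
    if t_sd == 0.0:
        logger.warning("null ensemble triangle count has zero variance: MZ set to 0")
        return 0.0
    return float((t_real - t_mean) / t_sd)


def hierarchy_coefficient(net) -> float:
    """HC: beta from the least-squares fit log C(k) = -beta log k + const.

    C(k) is the mean local clustering of degree-k nodes, over nodes with
    degree >= 2 and positive clustering.  Hierarchical networks show
    clustering that decays with degree (beta > 0).  Fewer than two distinct
    qualifying degrees -> 0."""
    g = _graph(net)
    clust = nx.clustering(g)
    by_degree: dict[int, list[float]] = {}
    for node, c in clust.items():
        k = g.degree(node)
        if k >= 2 and c > 0:
            by_degree.setdefault(k, []).append(c)
    if len(by_degree) < 2:
        logger.warning("fewer than 2 qualifying degrees: hierarchy coefficient set to 0")
        return 0.0
    ks = np.array(sorted(by_degree))
    cs = np.array([np.mean(by_degree[k]) for k in ks])
    slope, _ = np.polyfit(np.log(ks), np.log(cs), 1)
    return float(-slope)


def graph_index_complexity(net) -> float:
    """GIC: 4 c (1 - c) with c the adjacency spectral radius normalized
    between the path-graph (2 cos(pi/(n+1))) and complete-graph (n-1)
    extremes.  0 for both extremes, maximal for intermediate complexity."""
    g = _graph(net)
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    a = nx.to_numpy_array(g)
    lam_max = float(np.linalg.eigvalsh(a)[-1])
    lo = 2.0 * np.cos(np.pi / (n + 1))
    # sparse disconnected graphs can fall below the path-graph floor; clamp
    # so the complexity of sub-path spectra (e.g. edgeless) is 0, not negative
    c = np.clip((lam_max - lo) / (n - 1 - lo), 0.0, 1.0)
    return float(4.0 * c * (1.0 - c))


def feature_vector(net, ens: NullEnsembleSpec = NullEnsembleSpec()) -> np.ndarray:
    """All 14 features in the canonical order as a float vector.

    Deterministic given ``ens.seed``; never NaN (degenerate cases are 0).
    """
    g = _graph(net)
    dg = degree_mean(g)
    nb, eb = betweenness(g)
    cc, tt = clustering_transitivity(g)
    spl, ge = path_metrics(g)
    le = local_efficiency(g)
    ac = assortativity(g)
    sw = small_worldness(g, ens)
    md = modularity(g)
    mz = motif_zscore(g, ens)
    hc = hierarchy_coefficient(g)
    gic = graph_index_complexity(g)
    vec = np.array([dg, nb, cc, spl, eb, ge, le, tt, ac, sw, md, mz, hc, gic])
    assert np.isfinite(vec).all()
    return vec
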