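"""The 14 graph-topology features against closed forms and brute force."""

import itertools

import networkx as nx
import numpy as np
import pytest

from psiselect.connectivity import BinaryNetwork
from psiselect.graph_features import (
    FEATURE_NAMES,
    NullEnsembleSpec,
    assortativity,
    betweenness,
    clustering_transitivity,
    degree_mean,
    feature_vector,
    graph_index_complexity,
    hierarchy_coefficient,
    local_efficiency,
    modularity,
    motif_zscore,
    path_metrics,
    small_worldness,
)

from conftest import (
    brute_assortativity,
    brute_betweenness,
    brute_cc_tt,
    brute_local_efficiency,
    brute_spl_ge,
    random_adjacency,
)


def net_of(g: nx.Graph) -> BinaryNetwork:
    return BinaryNetwork(nx.to_numpy_array(g).astype(int))


class TestClosedForms:
    def test_degree(self):
        assert degree_mean(net_of(nx.complete_graph(4))) == 3.0
        assert degree_mean(net_of(nx.cycle_graph(5))) == 2.0
        assert degree_mean(net_of(nx.empty_graph(5))) == 0.0

    def test_node_betweenness_path3(self):
        nb, _ = betweenness(net_of(nx.path_graph(3)))
        assert nb == pytest.approx(1.0 / 3.0)

    def test_node_betweenness_complete(self):
        nb, _ = betweenness(net_of(nx.complete_graph(4)))
        assert nb == 0.0

    def test_star_edges_equally_between(self):
        g = nx.star_graph(4)  # S4: centre + 4 leaves
        ebc = nx.edge_betweenness_centrality(g, normalized=False)
        assert len(set(round(v, 9) for v in ebc.values())) == 1
        _, eb = betweenness(net_of(g))
        assert eb == pytest.approx(next(iter(ebc.values())))

    def test_clustering_extremes(self):
        for n in (4, 5):
            cc, tt = clustering_transitivity(net_of(nx.complete_graph(n)))
            assert (cc, tt) == (1.0, 1.0)
        cc, tt = clustering_transitivity(net_of(nx.random_labeled_tree(8, seed=1)))
        assert (cc, tt) == (0.0, 0.0)

    def test_path_metrics_p3(self):
        spl, ge = path_metrics(net_of(nx.path_graph(3)))
        assert spl == pytest.approx(4.0 / 3.0)
        assert ge == pytest.approx(5.0 / 6.0)

    def test_path_metrics_disconnected_edges(self):
        g = nx.Graph([(0, 1), (2, 3)])
        spl, ge = path_metrics(net_of(g))
        assert spl == pytest.approx(1.0)  # reachable pairs only
        assert ge == pytest.approx(2.0 / 6.0)

    def test_local_efficiency_extremes(self):
        assert local_efficiency(net_of(nx.complete_graph(4))) == pytest.approx(1.0)
        assert local_efficiency(net_of(nx.star_graph(4))) == 0.0

    def test_assortativity_star_is_minus_one(self):
        assert assortativity(net_of(nx.star_graph(5))) == pytest.approx(-1.0)

    def test_assortativity_regular_graph_degenerate(self):
        assert assortativity(net_of(nx.cycle_graph(6))) == 0.0

    def test_modularity_two_cliques(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        assert modularity(net_of(g)) == pytest.approx(0.5)

    def test_modularity_complete_graph_zero(self):
        assert modularity(net_of(nx.complete_graph(6))) == pytest.approx(0.0, abs=1e-12)

    def test_modularity_near_exhaustive_optimum(self):
        """Greedy Q on two bridged K5s agrees with brute-force search over
        all partitions into <= 3 parts."""
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        g.add_edge(0, 5)
        best = -1.0
        nodes = list(g.nodes)
        for labels in itertools.product(range(3), repeat=len(nodes) - 1):
            labels = (0,) + labels
            parts = [
                {n for n, l in zip(nodes, labels) if l == k} for k in range(3)
            ]
            parts = [p for p in parts if p]
            best = max(best, nx.community.modularity(g, parts))
        assert modularity(net_of(g)) == pytest.approx(best, abs=0.02)

    def test_gic_path_and_complete_are_zero(self):
        for n in (4, 6, 9):
            assert graph_index_complexity(net_of(nx.path_graph(n))) == pytest.approx(0.0, abs=1e-9)
            assert graph_index_complexity(net_of(nx.complete_graph(n))) == pytest.approx(0.0, abs=1e-9)

    def test_gic_cycle_matches_direct_eigendecomposition(self):
        g = nx.cycle_graph(6)
        lam = np.linalg.eigvalsh(nx.to_numpy_array(g))[-1]
        assert lam == pytest.approx(2.0)
        lo = 2 * np.cos(np.pi / 7)
        c = (lam - lo) / (5 - lo)
        assert graph_index_complexity(net_of(g)) == pytest.approx(4 * c * (1 - c))


class TestHierarchyCoefficient:
    def test_uniform_clustering_gives_zero_slope(self):
        # two cliques of different size: C(k) = 1 for both degrees
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(5))
        assert hierarchy_coefficient(net_of(g)) == pytest.approx(0.0, abs=1e-9)

    def test_diamond_graph_follows_inverse_power_law(self):
        """K4 minus one edge has C(2) = 1 and C(3) = 2/3, which lies exactly
        on C(k) ~ k^-1, so the fitted exponent is 1."""
        g = nx.complete_graph(4)
        g.remove_edge(0, 1)
        assert hierarchy_coefficient(net_of(g)) == pytest.approx(1.0, abs=1e-6)

    def test_hierarchical_graph_positive(self):
        """Three K4 modules whose entry nodes form a triangle: hub-like
        nodes have higher degree but lower clustering, so C(k) decays."""
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        g = nx.disjoint_union(g, nx.complete_graph(4))
        g.add_edges_from([(0, 4), (4, 8), (8, 0)])
        assert hierarchy_coefficient(net_of(g)) > 0.0

    def test_too_few_degrees_returns_zero(self):
        assert hierarchy_coefficient(net_of(nx.complete_graph(4))) == 0.0


class TestNullModelFeatures:
    def test_unrewirable_graph_self_normalizes_to_one(self):
        # the complete graph cannot be rewired: the ensemble is the graph itself
        assert small_worldness(net_of(nx.complete_graph(5)), NullEnsembleSpec(5, 2, 0)) == pytest.approx(1.0)

    def test_watts_strogatz_ring_is_small_world(self):
        g = nx.watts_strogatz_graph(16, 4, 0.1, seed=3)
        sw = small_worldness(net_of(g), NullEnsembleSpec(20, 10, 1))
        assert sw > 1.0

    def test_erdos_renyi_near_one(self):
        vals = []
        for s in range(10):
            g = nx.erdos_renyi_graph(16, 0.4, seed=s)
            vals.append(small_worldness(net_of(g), NullEnsembleSpec(15, 10, s)))
        assert abs(np.median(vals) - 1.0) < 0.3

    def test_motif_zscore_positive_for_clustered_graph(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        g.add_edge(0, 5)
        vals = [
            motif_zscore(net_of(g), NullEnsembleSpec(20, 10, s)) for s in range(20)
        ]
        assert np.median(vals) > 0.0

    def test_motif_zscore_sign_stable_under_bigger_ensemble(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        g.add_edge(0, 5)
        small = motif_zscore(net_of(g), NullEnsembleSpec(20, 10, 5))
        big = motif_zscore(net_of(g), NullEnsembleSpec(200, 10, 5))
        assert np.sign(small) == np.sign(big)

    def test_deterministic_given_seed(self):
        g = nx.erdos_renyi_graph(12, 0.3, seed=9)
        ens = NullEnsembleSpec(20, 10, 42)
        assert small_worldness(net_of(g), ens) == small_worldness(net_of(g), ens)
        assert motif_zscore(net_of(g), ens) == motif_zscore(net_of(g), ens)


class TestBruteForceAgreement:
    @pytest.mark.parametrize("seed", range(12))
    def test_random_small_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        adj = random_adjacency(rng, n, float(rng.uniform(0.2, 0.9)))
        net = BinaryNetwork(adj)
        nb, eb = betweenness(net)
        bnb, beb = brute_betweenness(adj)
        assert nb == pytest.approx(bnb, abs=1e-9)
        assert eb == pytest.approx(beb, abs=1e-9)
        cc, tt = clustering_transitivity(net)
        bcc, btt = brute_cc_tt(adj)
        assert cc == pytest.approx(bcc, abs=1e-9)
        assert tt == pytest.approx(btt, abs=1e-9)
        spl, ge = path_metrics(net)
        bspl, bge = brute_spl_ge(adj)
        assert spl == pytest.approx(bspl, abs=1e-9)
        assert ge == pytest.approx(bge, abs=1e-9)
        assert local_efficiency(net) == pytest.approx(brute_local_efficiency(adj), abs=1e-9)
        assert assortativity(net) == pytest.approx(brute_assortativity(adj), abs=1e-9)


class TestFeatureVector:
    def test_edgeless_graph_all_zero(self):
        vec = feature_vector(net_of(nx.empty_graph(6)), NullEnsembleSpec(5, 2, 0))
        np.testing.assert_array_equal(vec, 0.0)

    def test_order_and_length(self):
        vec = feature_vector(net_of(nx.complete_graph(4)), NullEnsembleSpec(5, 2, 0))
        assert vec.shape == (14,)
        named = dict(zip(FEATURE_NAMES, vec))
        assert named["DG"] == 3.0
        assert named["CC"] == 1.0
        assert named["SPL"] == 1.0
        assert named["GE"] == 1.0

    def test_deterministic_entries_isomorphism_invariant(self):
        """Relabelling nodes leaves the 12 ensemble-free metrics unchanged."""
        rng = np.random.default_rng(17)
        adj = random_adjacency(rng, 8, 0.45)
        perm = rng.permutation(8)
        adj_p = adj[np.ix_(perm, perm)]
        ens = NullEnsembleSpec(5, 2, 0)
        v1 = feature_vector(BinaryNetwork(adj), ens)
        v2 = feature_vector(BinaryNetwork(adj_p), ens)
        stochastic = {FEATURE_NAMES.index("SW"), FEATURE_NAMES.index("MZ")}
        for i in range(14):
            if i not in stochastic:
                assert v1[i] == pytest.approx(v2[i], abs=1e-9), FEATURE_NAMES[i]

    @pytest.mark.parametrize("seed", range(5))
    def test_adding_edge_never_decreases_degree_or_efficiency(self, seed):
        rng = np.random.default_rng(seed)
        adj = random_adjacency(rng, 7, 0.3)
        free = np.argwhere(np.triu(1 - adj, 1))
        if free.size == 0:
            return
        i, j = free[rng.integers(len(free))]
        adj2 = adj.copy()
        adj2[i, j] = adj2[j, i] = 1
        assert degree_mean(BinaryNetwork(adj2)) >= degree_mean(BinaryNetwork(adj))
        _, ge1 = path_metrics(BinaryNetwork(adj))
        _, ge2 = path_metrics(BinaryNetwork(adj2))
        assert ge2 >= ge1 - 1e-12

    def test_never_nan_even_for_degenerate_graphs(self):
        cases = [nx.empty_graph(4), nx.path_graph(2), nx.star_graph(3)]
        for g in cases:
            vec = feature_vector(net_of(g), NullEnsembleSpec(5, 2, 0))
            assert np.isfinite(vec).all()
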