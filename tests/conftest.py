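"""Shared fixtures and independent brute-force oracles.

The graph oracles below recompute path- and triangle-based metrics by
explicit enumeration (DFS over all simple paths, triple loops), entirely
independent of the library code they check; they are only feasible for the
tiny graphs (n <= 6) the oracle tests use.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest


# ---------------------------------------------------------------------------
# brute-force graph metrics (adjacency matrix in, scalars out)

def _all_simple_paths(adj: np.ndarray, s: int, t: int) -> list[list[int]]:
    n = adj.shape[0]
    out: list[list[int]] = []

    def extend(path: list[int]) -> None:
        u = path[-1]
        if u == t:
            out.append(path)
            return
        for v in range(n):
            if adj[u, v] and v not in path:
                extend(path + [v])

    extend([s])
    return out


def _shortest_paths(adj: np.ndarray, s: int, t: int) -> list[list[int]]:
    paths = _all_simple_paths(adj, s, t)
    if not paths:
        return []
    d = min(len(p) for p in paths)
    return [p for p in paths if len(p) == d]


def brute_geodesics(adj: np.ndarray) -> dict[tuple[int, int], list[list[int]]]:
    n = adj.shape[0]
    return {
        (s, t): _shortest_paths(adj, s, t)
        for s in range(n)
        for t in range(n)
        if s != t
    }


def brute_spl_ge(adj: np.ndarray) -> tuple[float, float]:
    """Mean geodesic over reachable ordered pairs; global efficiency over all
    ordered pairs with 1/inf = 0."""
    n = adj.shape[0]
    geo = brute_geodesics(adj)
    dists = [len(ps[0]) - 1 for ps in geo.values() if ps]
    spl = float(np.mean(dists)) if dists else 0.0
    inv = [1.0 / (len(ps[0]) - 1) if ps else 0.0 for ps in geo.values()]
    ge = float(np.sum(inv)) / (n * (n - 1)) if n > 1 else 0.0
    return spl, ge


def brute_betweenness(adj: np.ndarray) -> tuple[float, float]:
    """Mean raw node betweenness and mean edge betweenness by enumerating
    every geodesic of every unordered pair."""
    n = adj.shape[0]
    geo = brute_geodesics(adj)
    node_b = np.zeros(n)
    edges = [(i, j) for i in range(n) for j in range(i + 1, n) if adj[i, j]]
    edge_b = {e: 0.0 for e in edges}
    for s in range(n):
        for t in range(s + 1, n):
            paths = geo[(s, t)]
            if not paths:
                continue
            k = len(paths)
            for p in paths:
                for v in p[1:-1]:
                    node_b[v] += 1.0 / k
                for a, b in zip(p[:-1], p[1:]):
                    edge_b[(min(a, b), max(a, b))] += 1.0 / k
    nb = float(node_b.mean())
    eb = float(np.mean(list(edge_b.values()))) if edges else 0.0
    return nb, eb


def brute_cc_tt(adj: np.ndarray) -> tuple[float, float]:
    n = adj.shape[0]
    local = np.zeros(n)
    for v in range(n):
        nbrs = [u for u in range(n) if adj[v, u]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            adj[a, b] for a, b in itertools.combinations(nbrs, 2)
        )
        local[v] = 2.0 * links / (k * (k - 1))
    triangles = sum(
        adj[a, b] and adj[b, c] and adj[a, c]
        for a, b, c in itertools.combinations(range(n), 3)
    )
    triples = sum(
        adj[v, a] and adj[v, b]
        for v in range(n)
        for a, b in itertools.combinations(range(n), 2)
        if a != v and b != v
    )
    tt = 3.0 * triangles / triples if triples else 0.0
    return float(local.mean()), float(tt)


def brute_local_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    vals = np.zeros(n)
    for v in range(n):
        nbrs = [u for u in range(n) if adj[v, u]]
        if len(nbrs) < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        _, ge = brute_spl_ge(sub)
        vals[v] = ge
    return float(vals.mean())


def brute_assortativity(adj: np.ndarray) -> float:
    n = adj.shape[0]
    deg = adj.sum(axis=1)
    xs, ys = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j]:
                xs.extend([deg[i], deg[j]])
                ys.extend([deg[j], deg[i]])
    if not xs:
        return 0.0
    xs, ys = np.array(xs, float), np.array(ys, float)
    if np.ptp(xs) == 0.0:
        return 0.0
    return float(np.corrcoef(xs, ys)[0, 1])


def random_adjacency(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, k=1)
    return (adj | adj.T).astype(int)


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture(scope="session")
def planted_ds_strong():
    """Well-separated planted table (effect size 4, 5 of 20 informative)."""
    from psiselect.synthetic import PlantedFeatureSpec, generate_planted_features

    return generate_planted_features(
        PlantedFeatureSpec(n_samples=360, n_features=20,
                           informative_idx=(0, 1, 2, 3, 4), effect_size=4.0, seed=7)
    )


@pytest.fixture(scope="session")
def tiny_epochs():
    """Small two-group epoch set for pipeline tests (4 channels, 128 Hz, 2 s)."""
    from psiselect.synthetic import CoupledSignalSpec, generate_coupled_epochs

    spec = CoupledSignalSpec(
        n_channels=4, fs=128.0, epoch_len=2.0, n_epochs_per_group=6,
        band_coupling={"delta": (0.5, 0.5), "alpha": (0.2, 0.8)},
        noise_sd=0.1, seed=11,
    )
    return generate_coupled_epochs(spec)
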