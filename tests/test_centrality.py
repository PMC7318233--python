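"""Centrality indices against closed forms and a brute-force path oracle."""

import itertools

import numpy as np
import pytest

import symptomnet as sn
from symptomnet.network import NetworkModel


def _model(W, codes=None):
    p = W.shape[0]
    codes = codes or tuple("ABCDEFGHIJ"[:p])
    return NetworkModel(
        weights=W, item_codes=codes, lambda_selected=0.1, ebic=0.0,
        ebic_gamma=0.5, n_effective=100, nonzero_edges=0,
    )


def brute_force_paths(W):
    """All-pairs shortest distances and shortest-path sets by enumeration.

    Distances are 1/|w|; every simple path is enumerated, so this oracle is
    independent of any graph-library routine.
    """
    p = W.shape[0]
    dist = np.full((p, p), np.inf)
    np.fill_diagonal(dist, 0.0)
    paths = {}
    for s in range(p):
        for t in range(p):
            if s == t:
                continue
            best, best_paths = np.inf, []
            inner = [v for v in range(p) if v not in (s, t)]
            for r in range(len(inner) + 1):
                for mid in itertools.permutations(inner, r):
                    route = (s, *mid, t)
                    ok = all(W[a, b] != 0 for a, b in zip(route, route[1:]))
                    if not ok:
                        continue
                    d = sum(1.0 / abs(W[a, b]) for a, b in zip(route, route[1:]))
                    if d < best - 1e-12:
                        best, best_paths = d, [route]
                    elif abs(d - best) <= 1e-12:
                        best_paths.append(route)
            dist[s, t] = best
            paths[(s, t)] = best_paths
    return dist, paths


def oracle_closeness(W):
    p = W.shape[0]
    dist, _ = brute_force_paths(W)
    out = np.zeros(p)
    for i in range(p):
        finite = [dist[i, j] for j in range(p) if j != i and np.isfinite(dist[i, j])]
        if finite:
            out[i] = (len(finite) / (p - 1)) / sum(finite)
    return out


def oracle_betweenness(W):
    p = W.shape[0]
    _, paths = brute_force_paths(W)
    out = np.zeros(p)
    for (s, t), routes in paths.items():
        if s >= t or not routes:
            continue
        for route in routes:
            for v in route[1:-1]:
                out[v] += 1.0 / len(routes)
    return out


class TestStrength:
    def test_star_graph(self):
        W = np.zeros((5, 5))
        for leaf in range(1, 5):
            W[0, leaf] = W[leaf, 0] = 0.5
        s = sn.strength(_model(W))
        assert s[0] == pytest.approx(2.0)
        np.testing.assert_allclose(s[1:], 0.5)

    def test_disconnected_node_zero(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.4
        assert sn.strength(_model(W))[2] == 0.0

    def test_absolute_values_by_default(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.3
        W[0, 2] = W[2, 0] = -0.4
        assert sn.strength(_model(W))[0] == pytest.approx(0.7)
        assert sn.strength(_model(W), signed=True)[0] == pytest.approx(-0.1)

    def test_adding_edge_never_decreases_strength(self, rng):
        W = np.abs(rng.normal(scale=0.2, size=(5, 5)))
        W = np.triu(W, 1) + np.triu(W, 1).T
        base = sn.strength(_model(W))
        W2 = W.copy()
        W2[0, 1] = W2[1, 0] = W[0, 1] + 0.3
        boosted = sn.strength(_model(W2))
        assert boosted[0] >= base[0] and boosted[1] >= base[1]


class TestShortestPathIndices:
    def test_path_graph_closeness(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        W[1, 2] = W[2, 1] = 0.5
        c = sn.closeness(_model(W))
        # d(A,B)=2, d(A,C)=4 -> closeness(A) = 1/6; middle node closer
        assert c[0] == pytest.approx(1.0 / 6.0)
        assert c[1] == pytest.approx(1.0 / 4.0)
        assert c[1] > c[0]

    def test_path_graph_betweenness(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        W[1, 2] = W[2, 1] = 0.5
        b = sn.betweenness(_model(W))
        np.testing.assert_allclose(b, [0.0, 1.0, 0.0])

    def test_complete_uniform_graph_zero_betweenness(self):
        W = np.full((4, 4), 0.3)
        np.fill_diagonal(W, 0.0)
        np.testing.assert_allclose(sn.betweenness(_model(W)), 0.0)

    def test_isolated_node_closeness_zero(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.4
        assert sn.closeness(_model(W))[2] == 0.0

    def test_matches_brute_force_oracle_on_random_networks(self, rng):
        for _ in range(6):
            A = rng.normal(scale=0.3, size=(6, 6))
            A[np.abs(A) < 0.15] = 0.0  # keep some structure sparse
            W = np.triu(A, 1) + np.triu(A, 1).T
            model = _model(W)
            np.testing.assert_allclose(
                sn.closeness(model), oracle_closeness(W), atol=1e-10
            )
            np.testing.assert_allclose(
                sn.betweenness(model), oracle_betweenness(W), atol=1e-8
            )

    def test_unit_weights_recover_classical_definitions(self):
        # 4-cycle with unit weights: closeness and betweenness equal the
        # textbook unweighted values
        W = np.zeros((4, 4))
        for i, j in [(0, 1), (1, 2), (2, 3), (3, 0)]:
            W[i, j] = W[j, i] = 1.0
        c = sn.closeness(_model(W))
        b = sn.betweenness(_model(W))
        np.testing.assert_allclose(c, 1.0 / 4.0)  # distances 1,1,2 -> 3/(p-1)=1
        np.testing.assert_allclose(b, 0.5)  # two shortest routes across


class TestCentralityTable:
    def test_permutation_equivariance(self, rng):
        A = rng.normal(scale=0.3, size=(5, 5))
        W = np.triu(A, 1) + np.triu(A, 1).T
        codes = tuple("ABCDE")
        perm = [2, 0, 4, 1, 3]
        Wp = W[np.ix_(perm, perm)]
        codes_p = tuple(codes[i] for i in perm)
        t1 = sn.centrality_table(_model(W, codes)).to_frame()
        t2 = sn.centrality_table(_model(Wp, codes_p)).to_frame()
        for col in ("strength", "closeness", "betweenness"):
            for code in codes:
                assert t1.loc[code, col] == pytest.approx(t2.loc[code, col], abs=1e-10)

    def test_zscores_and_dense_ranks(self, hub_chain_network):
        tab = sn.centrality_table(hub_chain_network).to_frame()
        for name in ("strength", "closeness", "betweenness"):
            z = tab[f"{name}_z"]
            assert z.mean() == pytest.approx(0.0, abs=1e-12)
            assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)
            ranks = tab[f"{name}_rank"]
            assert ranks.min() == 1
            assert set(ranks) == set(range(1, ranks.max() + 1))  # dense

    def test_top_selection(self, hub_chain_network):
        tab = sn.centrality_table(hub_chain_network)
        top = tab.top("strength", 3)
        s = tab.raw("strength")
        assert list(s[top]) == sorted(s, reverse=True)[:3]
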