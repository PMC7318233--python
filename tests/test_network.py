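"""Network estimation: glasso oracle equivalence, EBIC selection, layout."""

import warnings

import numpy as np
import pytest
from scipy.optimize import minimize

import symptomnet as sn
from symptomnet.network import (
    EDGE_TOL,
    NetworkModel,
    ebic_value,
    lambda_path,
)


def penalized_objective(K, S, lam):
    """-logdet K + tr(S K) + lam * ||K||_1,offdiag (to be minimized)."""
    sign, ld = np.linalg.slogdet(K)
    if sign <= 0:
        return np.inf
    return -ld + np.trace(S @ K) + lam * np.sum(np.abs(K - np.diag(np.diag(K))))


def oracle_minimum_3x3(S, lam):
    """Generic-optimizer oracle: Nelder-Mead over the Cholesky factor."""

    def unpack(theta):
        L = np.zeros((3, 3))
        L[np.tril_indices(3)] = theta
        return L @ L.T

    def f(theta):
        return penalized_objective(unpack(theta), S, lam)

    x0 = np.linalg.cholesky(np.linalg.inv(S))[np.tril_indices(3)]
    res = minimize(
        f, x0, method="Nelder-Mead",
        options={"maxiter": 8000, "xatol": 1e-10, "fatol": 1e-12},
    )
    return res.fun


def random_correlation_3x3(rng):
    A = rng.normal(size=(3, 6))
    S = np.corrcoef(A)
    return S


def _model_from_weights(W, codes=None):
    p = W.shape[0]
    codes = codes or tuple("ABCDEFGHIJ"[:p])
    return NetworkModel(
        weights=W, item_codes=codes, lambda_selected=0.1, ebic=0.0,
        ebic_gamma=0.5, n_effective=100,
        nonzero_edges=int(np.sum(np.abs(W[np.triu_indices(p, 1)]) > EDGE_TOL)),
    )


class TestGlassoFit:
    def test_identity_input_gives_identity_precision(self):
        for lam in (0.0, 0.1, 0.5):
            K = sn.glasso_fit(np.eye(4), lam)
            np.testing.assert_allclose(K, np.eye(4), atol=1e-10)

    def test_full_sparsity_at_lambda_max(self, rng):
        S = random_correlation_3x3(rng)
        lam_max = np.abs(S - np.eye(3)).max()
        K = sn.glasso_fit(S, lam_max * 1.000001)
        off = K - np.diag(np.diag(K))
        assert np.all(off == 0.0)

    def test_matches_generic_optimizer_on_3node_problems(self, rng):
        """Penalized likelihood within 1e-6 of the Nelder-Mead oracle."""
        for _ in range(10):
            S = random_correlation_3x3(rng)
            for lam in (0.05, 0.15):
                K = sn.glasso_fit(S, lam)
                mine = penalized_objective(K, S, lam)
                oracle = oracle_minimum_3x3(S, lam)
                assert mine <= oracle + 1e-6

    def test_precision_is_pd_along_path(self, hub_chain_cohort):
        est = sn.TetrachoricCorrelation().fit(hub_chain_cohort)
        S = est.rho_
        for lam in lambda_path(S, 20):
            K = sn.glasso_fit(S, lam)
            assert np.linalg.eigvalsh(K).min() > 0

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            sn.glasso_fit(np.eye(3), -0.1)


class TestPrecisionToPartial:
    def test_diagonal_precision_gives_zero_weights(self):
        W = sn.precision_to_partial(np.diag([2.0, 3.0, 1.0]))
        assert np.all(W == 0.0)

    def test_closed_form_2x2(self):
        W = sn.precision_to_partial(np.array([[1.0, -0.5], [-0.5, 1.0]]))
        assert W[0, 1] == pytest.approx(0.5, abs=1e-12)
        assert W[0, 0] == 0.0

    def test_random_pd_precision_bounded_and_symmetric(self, rng):
        for _ in range(20):
            A = rng.normal(size=(4, 8))
            K = A @ A.T + 0.5 * np.eye(4)
            W = sn.precision_to_partial(K)
            np.testing.assert_allclose(W, W.T, atol=1e-12)
            assert np.abs(W).max() < 1.0  # Cauchy-Schwarz on the inverse

    def test_nonpositive_diagonal_rejected(self):
        with pytest.raises(ValueError):
            sn.precision_to_partial(np.array([[0.0, 0.1], [0.1, 1.0]]))


class TestEBICSelection:
    def test_identity_correlation_selects_empty_network(self):
        model = sn.select_ebic(np.eye(5), n=500)
        assert model.nonzero_edges == 0
        assert (model.path.n_edges == 0).all()

    def test_single_lambda_path_returns_that_lambda(self):
        model = sn.select_ebic(np.eye(4), n=100, lambdas=[0.3])
        assert model.lambda_selected == pytest.approx(0.3)

    def test_edge_count_monotone_in_lambda(self, hub_chain_network):
        path = hub_chain_network.path.sort_values("lambda", ascending=False)
        counts = path.n_edges.to_numpy()
        assert np.all(np.diff(counts) >= 0)  # descending lambda, growing edges

    def test_recovers_planted_edges(self, matching_cohort, matching_structure):
        """Sensitivity >= 0.8 and FPR <= 0.2 on the planted sparse network."""
        _, _, true_edges = matching_structure
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sn.estimate_network(matching_cohort)
        p = model.p
        est = {
            (i, j)
            for i in range(p)
            for j in range(i + 1, p)
            if abs(model.weights[i, j]) > EDGE_TOL
        }
        truth = set(true_edges)
        sens = len(est & truth) / len(truth)
        fpr = len(est - truth) / (p * (p - 1) // 2 - len(truth))
        assert sens >= 0.8
        assert fpr <= 0.2

    def test_ebic_formula_components(self):
        # hand-checkable 2-node case: E in {0, 1}, penalty terms explicit
        S = np.array([[1.0, 0.4], [0.4, 1.0]])
        K = sn.glasso_fit(S, 0.01)
        n, gamma, p = 200, 0.5, 2
        E = 1
        sign, ld = np.linalg.slogdet(K)
        expected = -n * (ld - np.trace(S @ K)) + E * np.log(n) + 4 * E * gamma * np.log(p)
        assert ebic_value(K, S, n, gamma) == pytest.approx(expected, abs=1e-9)

    def test_determinism(self, matching_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = sn.estimate_network(matching_cohort)
            b = sn.estimate_network(matching_cohort)
        np.testing.assert_array_equal(a.weights, b.weights)
        assert a.lambda_selected == b.lambda_selected


class TestEdgeBookkeeping:
    def test_possible_edges_for_ten_nodes(self):
        W = np.zeros((10, 10))
        nonzero, possible, pct = sn.count_edges(_model_from_weights(W, tuple("ABCDEFGHIJ")))
        assert (nonzero, possible, pct) == (0, 45, 0.0)

    @pytest.mark.parametrize(
        "nonzero,expected_pct", [(29, 64.4), (34, 75.6), (33, 73.3), (22, 48.9)]
    )
    def test_edge_percentage_one_decimal(self, nonzero, expected_pct):
        W = np.zeros((10, 10))
        pairs = [(i, j) for i in range(10) for j in range(i + 1, 10)][:nonzero]
        for i, j in pairs:
            W[i, j] = W[j, i] = 0.1
        _, possible, pct = sn.count_edges(_model_from_weights(W, tuple("ABCDEFGHIJ")))
        assert possible == 45
        assert pct == expected_pct

    def test_top_associations_order_and_tiebreak(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.5
        W[2, 3] = W[3, 2] = -0.5  # same magnitude: lexicographic tie-break
        W[0, 2] = W[2, 0] = 0.3
        model = _model_from_weights(W)
        top = sn.top_associations(model, 3)
        assert top[0][:2] == ("A", "B")
        assert top[1][:2] == ("C", "D")
        assert top[2][:2] == ("A", "C")

    def test_top_associations_overflow_warns(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.2
        with pytest.warns(UserWarning, match="only 1"):
            top = sn.top_associations(_model_from_weights(W), 3)
        assert len(top) == 1


class TestLayout:
    def test_strong_edge_ends_closer_than_weak_edge(self):
        strong = np.array([[0.0, 0.9], [0.9, 0.0]])
        weak = np.array([[0.0, 0.05], [0.05, 0.0]])
        d = {}
        for name, W in (("strong", strong), ("weak", weak)):
            lay = sn.fruchterman_reingold(_model_from_weights(W), seed=3)
            d[name] = np.linalg.norm(lay.coordinates[0] - lay.coordinates[1])
        assert d["strong"] < d["weak"]

    def test_empty_network_spreads_nodes(self):
        lay = sn.fruchterman_reingold(_model_from_weights(np.zeros((4, 4))), seed=1)
        for i in range(4):
            for j in range(i + 1, 4):
                assert np.linalg.norm(lay.coordinates[i] - lay.coordinates[j]) > 0

    def test_seed_determinism(self, hub_chain_network):
        a = sn.fruchterman_reingold(hub_chain_network, seed=11)
        b = sn.fruchterman_reingold(hub_chain_network, seed=11)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)


class TestExports:
    def test_edge_tsv_matrix_csv_graphml(self, tmp_path, hub_chain_network):
        m = hub_chain_network
        m.to_edge_tsv(tmp_path / "edges.tsv")
        m.to_matrix_csv(tmp_path / "weights.csv")
        m.to_graphml(tmp_path / "net.graphml")
        import pandas as pd

        edges = pd.read_csv(tmp_path / "edges.tsv", sep="\t")
        assert len(edges) == m.nonzero_edges
        W = pd.read_csv(tmp_path / "weights.csv", index_col=0)
        np.testing.assert_allclose(W.to_numpy(), m.weights, atol=1e-12)
        import networkx as nx

        G = nx.read_graphml(tmp_path / "net.graphml")
        assert G.number_of_edges() == m.nonzero_edges
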