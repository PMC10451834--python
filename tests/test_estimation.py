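"""EBIC graphical-lasso estimation, covariate adjustment and similarity."""

import numpy as np
import pytest
from sklearn.covariance import graphical_lasso as sklearn_glasso

import symptomnet as sn
from symptomnet.association import CorrelationEstimate
from symptomnet.estimation import ebic, glasso_precision, lambda_path

from conftest import toy_network


def _corr(mat, n=500, labels=None):
    mat = np.asarray(mat, float)
    labels = labels or [f"N{i}" for i in range(mat.shape[0])]
    return CorrelationEstimate(mat, labels, n=n)


class TestGlassoPrecision:
    def test_identity_input_gives_identity_precision(self):
        fit = glasso_precision(np.eye(5), 0.1)
        assert np.allclose(fit.theta, np.eye(5))
        assert fit.edge_count == 0

    def test_penalty_dominance_disconnects(self):
        S = np.array([[1.0, 0.4, 0.2], [0.4, 1.0, 0.3], [0.2, 0.3, 1.0]])
        fit = glasso_precision(S, 0.4)
        off = fit.theta[np.triu_indices(3, 1)]
        assert np.all(off == 0.0)

    def test_equicorrelation_closed_form_at_zero_penalty(self):
        # inverse of a 3x3 equicorrelation matrix gives rho_partial = r/(1+r)
        r = 0.5
        S = np.full((3, 3), r)
        np.fill_diagonal(S, 1.0)
        fit = glasso_precision(S, 0.0)
        P = fit.partial_correlations()
        assert np.allclose(P[np.triu_indices(3, 1)], r / (1 + r), atol=1e-10)

    def test_matches_sklearn_solver(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((300, 7))
        X[:, 1] += 0.6 * X[:, 0]
        X[:, 5] += 0.5 * X[:, 2]
        S = np.corrcoef(X, rowvar=False)
        for lam in (0.2, 0.08, 0.02):
            ours = glasso_precision(S, lam).theta
            _, ref = sklearn_glasso(S, alpha=lam, tol=1e-10, max_iter=1000)
            assert np.abs(ours - ref).max() < 1e-4

    def test_zero_penalty_limit_equals_inverse_covariance(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=(200, 4))
        a[:, 3] += 0.5 * a[:, 0]
        S = np.corrcoef(a, rowvar=False)
        Theta_inv = np.linalg.inv(S)
        d = np.sqrt(np.diag(Theta_inv))
        oracle = -Theta_inv / np.outer(d, d)
        np.fill_diagonal(oracle, 0.0)
        fit = glasso_precision(S, 1e-7)
        assert np.abs(fit.partial_correlations() - oracle).max() < 1e-4

    def test_non_pd_input_rejected(self):
        S = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="positive definite"):
            glasso_precision(S, 0.1)


class TestEbic:
    def test_empty_graph_independent_of_gamma(self):
        fit = glasso_precision(np.eye(4), 0.3)
        assert ebic(fit, n=100, gamma=0.0) == ebic(fit, n=100, gamma=1.0)

    def test_gamma_difference_is_algebraic_identity(self):
        S = np.array([[1.0, 0.5, 0.1], [0.5, 1.0, 0.4], [0.1, 0.4, 1.0]])
        fit = glasso_precision(S, 0.05)
        E = fit.edge_count
        diff = ebic(fit, n=200, gamma=0.5) - ebic(fit, n=200, gamma=0.0)
        assert diff == pytest.approx(2.0 * E * np.log(3))

    def test_penalty_term_hand_computed(self):
        # E = 2 edges, n = 100, p = 3: penalty = 2 log 100 + 4*gamma*2*log 3
        S = np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 0.4], [0.0, 0.4, 1.0]])
        fit = glasso_precision(S, 0.12)
        assert fit.edge_count == 2
        for gamma in (0.0, 0.25, 0.5):
            penalty = ebic(fit, 100, gamma) + 2 * (0.5 * 100 * fit.loglik)
            expected = 2 * np.log(100) + 4 * gamma * 2 * np.log(3)
            assert penalty == pytest.approx(expected, rel=1e-12)


class TestEstimateNetwork:
    def test_independent_data_recovers_mostly_empty_graph(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((2000, 9))
        S = np.corrcoef(X, rowvar=False)
        net = sn.estimate_network(_corr(S, n=2000))
        assert net.edge_count <= int(0.1 * 36)  # >= 90% of true zeros kept zero

    def test_chain_graph_edges_all_detected(self, chain_truth):
        em = sn.default_emulation(p=9, n=2000)
        data = sn.sample_ordinal_dataset(chain_truth, em, seed=3)
        net = sn.estimate_network(data)
        for i in range(8):
            assert net.weights[i, i + 1] != 0.0

    def test_edge_count_monotone_in_gamma(self, medium_dataset):
        e0 = sn.estimate_network(medium_dataset, gamma=0.0).edge_count
        e1 = sn.estimate_network(medium_dataset, gamma=1.0).edge_count
        assert e1 <= e0

    def test_edge_count_monotone_along_penalty_path(self, medium_dataset):
        est = sn.rank_correlation_matrix(medium_dataset)
        path = lambda_path(est.matrix, n_lambda=25)
        counts = [glasso_precision(est.matrix, lam).edge_count for lam in path]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_weights_symmetric_zero_diagonal(self, medium_dataset):
        net = sn.estimate_network(medium_dataset)
        assert np.allclose(net.weights, net.weights.T)
        assert np.all(np.diag(net.weights) == 0.0)
        assert np.abs(net.weights).max() < 1.0

    def test_parameter_recovery_median_over_seeds(self):
        # sparse truth, |w| in [0.2, 0.4]: estimated vs true upper-triangle
        # weight correlation should reach 0.8 at n = 2000 (median of seeds)
        iu = np.triu_indices(9, 1)
        cors = []
        for seed in range(5):
            truth = sn.make_true_network(
                sn.TrueNetworkSpec(p=9, density=0.3, weight_range=(0.2, 0.4), seed=seed)
            )
            em = sn.default_emulation(p=9, n=2000)
            data = sn.sample_ordinal_dataset(truth, em, seed=100 + seed)
            net = sn.estimate_network(data)
            cors.append(np.corrcoef(truth.weights[iu], net.weights[iu])[0, 1])
        assert np.median(cors) >= 0.8

    def test_serialization_roundtrip(self, medium_dataset, tmp_path):
        net = sn.estimate_network(medium_dataset)
        f = tmp_path / "net.json"
        net.to_json(f)
        back = sn.NetworkModel.from_json(f)
        assert back.nodes == net.nodes
        assert np.allclose(back.weights, net.weights)
        assert back.lam == pytest.approx(net.lam)


class TestCovariateAdjustment:
    def test_independent_covariate_leaves_network_similar(self, random_truth):
        import pandas as pd

        em = sn.default_emulation(p=9, n=1500)
        data = sn.sample_ordinal_dataset(random_truth, em, seed=21)
        rng = np.random.default_rng(0)
        cov = pd.DataFrame({"age": rng.normal(20, 1.5, len(data))})
        ds = sn.ItemDataset(data.values, None, cov)
        base = sn.estimate_network(ds)
        adj = sn.covariate_adjusted_network(ds, "age")
        assert adj.nodes == base.nodes
        r, _ = sn.network_similarity(base, adj)
        assert r > 0.95

    def test_duplicated_symptom_covariate_shrinks_its_edges(self):
        # conditioning on a copy of PHQ1 absorbs PHQ1's unique connections
        import pandas as pd

        truth = sn.make_true_network(sn.TrueNetworkSpec(p=9, density=0.3, seed=2))
        em = sn.default_emulation(p=9, n=1500)
        data = sn.sample_ordinal_dataset(truth, em, seed=22)
        noisy_copy = data.values["PHQ1"] + np.random.default_rng(1).normal(
            0, 0.05, len(data)
        )
        ds = sn.ItemDataset(data.values, None, pd.DataFrame({"dup": noisy_copy}))
        base = sn.estimate_network(ds)
        adj = sn.covariate_adjusted_network(ds, "dup")
        i = base.nodes.index("PHQ1")
        assert np.abs(adj.weights[i]).sum() < np.abs(base.weights[i]).sum()

    def test_constant_covariate_rejected(self, medium_dataset):
        import pandas as pd

        ds = sn.ItemDataset(
            medium_dataset.values, None, pd.DataFrame({"c": np.ones(len(medium_dataset))})
        )
        with pytest.raises(ValueError, match="constant"):
            sn.covariate_adjusted_network(ds, "c")


class TestNetworkSimilarity:
    def test_self_similarity_is_one(self, medium_dataset):
        net = sn.estimate_network(medium_dataset)
        r, p = sn.network_similarity(net, net)
        assert r == pytest.approx(1.0)

    def test_negated_network_gives_minus_one(self, medium_dataset):
        net = sn.estimate_network(medium_dataset)
        neg = sn.NetworkModel(net.nodes, -net.weights, net.lam, net.gamma, net.ebic, net.n)
        r, _ = sn.network_similarity(net, neg)
        assert r == pytest.approx(-1.0)

    def test_three_node_direct_computation(self):
        a = toy_network([[0, 0.3, 0.1], [0.3, 0, -0.2], [0.1, -0.2, 0]])
        b = toy_network([[0, 0.2, 0.0], [0.2, 0, -0.1], [0.0, -0.1, 0]])
        r, _ = sn.network_similarity(a, b)
        oracle = np.corrcoef([0.3, 0.1, -0.2], [0.2, 0.0, -0.1])[0, 1]
        assert r == pytest.approx(oracle)

    def test_mismatched_nodes_rejected(self, medium_dataset):
        net = sn.estimate_network(medium_dataset)
        other = toy_network(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="node set"):
            sn.network_similarity(net, other)
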