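"""Centrality indices, predictability and flow decomposition."""

import itertools

import numpy as np
import pandas as pd
import pytest

import symptomnet as sn
from conftest import toy_network


def star_network(w=0.5, leaves=4):
    W = np.zeros((leaves + 1, leaves + 1))
    W[0, 1:] = W[1:, 0] = w
    return toy_network(W)


# -- independent oracles ------------------------------------------------

def brute_force_betweenness(W):
    """Exhaustive simple-path enumeration of shortest-path betweenness on
    distances 1/|w| (fractional credit for ties)."""
    p = W.shape[0]
    with np.errstate(divide="ignore"):
        D = np.where(W != 0, 1.0 / np.abs(W), np.inf)
    btw = np.zeros(p)
    for s, t in itertools.combinations(range(p), 2):
        best, best_paths = np.inf, []
        # enumerate all simple paths s -> t
        stack = [(s, [s], 0.0)]
        while stack:
            node, path, dist = stack.pop()
            if dist > best + 1e-12:
                continue
            if node == t:
                if dist < best - 1e-12:
                    best, best_paths = dist, [path]
                elif abs(dist - best) <= 1e-12:
                    best_paths.append(path)
                continue
            for nxt in range(p):
                if np.isfinite(D[node, nxt]) and nxt not in path:
                    stack.append((nxt, path + [nxt], dist + D[node, nxt]))
        if not np.isfinite(best):
            continue
        for path in best_paths:
            for mid in path[1:-1]:
                btw[mid] += 1.0 / len(best_paths)
    return btw


def brute_force_bfs_layers(W, focal):
    adj = W != 0
    layers, seen, frontier = [], {focal}, [focal]
    while True:
        nxt = sorted(
            {j for i in frontier for j in np.flatnonzero(adj[i])} - seen
        )
        if not nxt:
            break
        layers.append(nxt)
        seen |= set(nxt)
        frontier = nxt
    unreached = sorted(set(range(W.shape[0])) - seen)
    return layers, unreached


class TestCentrality:
    def test_star_strength_and_betweenness(self):
        net = star_network(0.5, leaves=4)
        tab = sn.centrality_table(net)
        assert tab.loc["N0", "strength"] == pytest.approx(2.0)
        assert tab.loc["N1", "strength"] == pytest.approx(0.5)
        # all C(4,2) = 6 leaf pairs route through the hub
        assert tab.loc["N0", "betweenness"] == pytest.approx(6.0)
        assert tab.loc["N1", "betweenness"] == pytest.approx(0.0)

    def test_mixed_sign_strength_vs_expected_influence(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.3
        W[0, 2] = W[2, 0] = -0.2
        net = toy_network(W)
        assert sn.node_strength(net)[0] == pytest.approx(0.5)
        assert sn.expected_influence(net)[0] == pytest.approx(0.1)

    def test_strength_equals_ei_on_positive_networks(self, medium_dataset):
        net = sn.estimate_network(medium_dataset)
        pos = sn.NetworkModel(net.nodes, np.abs(net.weights))
        assert np.allclose(sn.node_strength(pos), sn.expected_influence(pos))

    def test_betweenness_matches_path_enumeration(self):
        rng = np.random.default_rng(17)
        for trial in range(8):
            p = rng.integers(4, 7)
            W = np.zeros((p, p))
            iu = np.triu_indices(p, 1)
            mask = rng.random(len(iu[0])) < 0.6
            vals = rng.uniform(0.1, 0.9, len(iu[0])) * np.where(
                rng.random(len(iu[0])) < 0.3, -1, 1
            )
            W[iu] = np.where(mask, vals, 0.0)
            W = W + W.T
            net = toy_network(W)
            tab = sn.centrality_table(net)
            oracle = brute_force_betweenness(W)
            assert np.allclose(tab["betweenness"].to_numpy(), oracle, atol=1e-9)

    def test_harmonic_closeness_isolated_node_zero(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        tab = sn.centrality_table(toy_network(W))
        assert tab.loc["N2", "closeness"] == 0.0
        assert tab.loc["N0", "closeness"] == pytest.approx(0.5)  # 1/d = |w|

    def test_zscores_standardized_across_nodes(self, medium_dataset):
        net = sn.estimate_network(medium_dataset)
        tab = sn.centrality_table(net)
        for col in ("z_strength", "z_expected_influence"):
            assert tab[col].mean() == pytest.approx(0.0, abs=1e-10)
            assert tab[col].std(ddof=0) == pytest.approx(1.0)


class TestGlobalStrength:
    def test_empty_network_zero(self):
        assert sn.global_strength(toy_network(np.zeros((4, 4)))) == 0.0

    def test_signed_edges_sum_absolutely(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.3
        W[1, 2] = W[2, 1] = -0.2
        assert sn.global_strength(toy_network(W)) == pytest.approx(0.5)

    def test_equals_half_sum_of_strengths(self, medium_dataset):
        net = sn.estimate_network(medium_dataset)
        assert sn.global_strength(net) == pytest.approx(
            sn.node_strength(net).sum() / 2.0
        )


class TestPredictability:
    def test_independent_item_near_zero(self):
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(
            {
                "A": rng.normal(size=5000),
                "B": rng.normal(size=5000),
                "C": rng.normal(size=5000),
            }
        )
        r2 = sn.predictability(sn.ItemDataset(vals))
        assert r2["A"] < 0.01

    def test_exact_copy_gives_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        vals = pd.DataFrame({"A": x, "B": x.copy(), "C": rng.normal(size=200)})
        r2 = sn.predictability(sn.ItemDataset(vals))
        assert r2["A"] == pytest.approx(1.0)

    def test_variance_decomposition_oracle(self):
        # y = 0.5 x + e with SD(e) = 0.5 SD(x): R^2 -> 0.25/(0.25+0.25) = 0.5
        rng = np.random.default_rng(2)
        x = rng.normal(size=100_000)
        y = 0.5 * x + rng.normal(scale=0.5, size=100_000)
        vals = pd.DataFrame({"X": x, "Y": y})
        r2 = sn.predictability(sn.ItemDataset(vals))
        assert r2["Y"] == pytest.approx(0.5, abs=0.01)

    def test_r2_bounded(self, medium_dataset):
        r2 = sn.predictability(medium_dataset)
        assert ((r2 >= 0) & (r2 <= 1)).all()


class TestFlowDecomposition:
    def test_forced_small_example(self):
        # F-A, A-B edges, C isolated
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.4
        W[1, 2] = W[2, 1] = 0.3
        net = toy_network(W, nodes=["F", "A", "B", "C"])
        dec = sn.flow_decompose(net, "F")
        assert dec.direct == ["A"]
        assert dec.indirect_layers == [["B"]]
        assert dec.unreached == ["C"]
        assert dec.edges_to_focal == [("A", 0.4)]

    def test_fully_connected_all_direct(self):
        W = np.full((5, 5), 0.2)
        np.fill_diagonal(W, 0.0)
        dec = sn.flow_decompose(toy_network(W), "N2")
        assert sorted(dec.direct) == ["N0", "N1", "N3", "N4"]
        assert dec.indirect_layers == []
        assert dec.unreached == []

    def test_direct_set_is_exact_neighborhood(self, medium_dataset):
        net = sn.estimate_network(medium_dataset)
        for focal in net.nodes:
            dec = sn.flow_decompose(net, focal)
            fi = net.nodes.index(focal)
            oracle = {net.nodes[j] for j in np.flatnonzero(net.weights[fi] != 0)}
            assert set(dec.direct) == oracle

    def test_layers_match_independent_bfs(self):
        rng = np.random.default_rng(23)
        W = np.zeros((10, 10))
        iu = np.triu_indices(10, 1)
        mask = rng.random(len(iu[0])) < 0.2
        W[iu] = np.where(mask, rng.uniform(0.1, 0.5, len(iu[0])), 0.0)
        W = W + W.T
        W[0, :] = W[:, 0] = np.where(np.arange(10) == 1, 0.3, 0.0)  # one focal edge
        net = toy_network(W)
        dec = sn.flow_decompose(net, "N0")
        layers, unreached = brute_force_bfs_layers(W, 0)
        got = [dec.direct] + dec.indirect_layers
        assert got == [[f"N{i}" for i in lay] for lay in layers]
        assert dec.unreached == [f"N{i}" for i in unreached]

    def test_partition_property(self, medium_dataset):
        net = sn.estimate_network(medium_dataset.select_items(list(sn.datasets.PHQ_ITEMS)))
        dec = sn.flow_decompose(net, "PHQ9")
        parts = dec.direct + sum(dec.indirect_layers, []) + dec.unreached
        assert sorted(parts) == sorted(n for n in net.nodes if n != "PHQ9")

    def test_unknown_focal_rejected(self, medium_dataset):
        net = sn.estimate_network(medium_dataset)
        with pytest.raises(KeyError):
            sn.flow_decompose(net, "nope")
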