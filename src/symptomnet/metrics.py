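"""Node-level and global indices of an estimated symptom network.

Strength is the sum of absolute edge weights at a node; expected influence
(EI) keeps the signs, so the two coincide on all-positive networks.
Closeness and betweenness operate on the distance transform
``d_ij = 1 / |w_ij|`` over nonzero edges: closeness is harmonic (sums of
inverse distances, so disconnected networks stay well defined) and
betweenness is shortest-path betweenness with fractional credit for ties.
Predictability is the in-sample R^2 of each item regressed on all others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .estimation import NetworkModel


def _distance_graph(net: NetworkModel) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    for i, a in enumerate(net.nodes):
        for j in range(i + 1, net.p):
            w = net.weights[i, j]
            if w != 0.0:
                g.add_edge(a, net.nodes[j], weight=w, distance=1.0 / abs(w))
    return g


def node_strength(net: NetworkModel) -> np.ndarray:
    return np.abs(net.weights).sum(axis=1)


def expected_influence(net: NetworkModel) -> np.ndarray:
    """One-step expected influence: signed sum of a node's edge weights."""
    return net.weights.sum(axis=1)


def global_strength(net: NetworkModel) -> float:
    """Sum of absolute edge weights over the strict upper triangle."""
    return float(np.abs(net.upper_triangle()).sum())


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x)
    if sd == 0:
        return np.zeros_like(x)
    return (x - np.mean(x)) / sd


def predictability(data, nodes: list[str] | None = None) -> pd.Series:
    """Per-node R^2 from ordinary least squares of each item on the rest.

    With collinear predictors the minimum-norm least-squares solution is
    used (``numpy.linalg.lstsq``), which leaves R^2 well defined.
    """
    cols = nodes or data.item_labels
    X = data.values[cols].to_numpy(dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need n > p + 1 subjects for nodewise regression")
    out = {}
    for j, name in enumerate(cols):
        y = X[:, j]
        Z = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        resid = y - Z @ beta
        tss = float(np.sum((y - y.mean()) ** 2))
        r2 = 0.0 if tss == 0 else 1.0 - float(np.sum(resid**2)) / tss
        out[name] = min(max(r2, 0.0), 1.0)
    return pd.Series(out, name="predictability")


def centrality_table(net: NetworkModel, data=None) -> pd.DataFrame:
    """Raw and standardized centrality indices, plus predictability if
    item-level data are supplied.

    Columns: strength, expected_influence, closeness (harmonic),
    betweenness, their z-scored versions, and optionally predictability.
    """
    if net.p < 2:
        raise ValueError("need at least 2 nodes")
    g = _distance_graph(net)
    strength = node_strength(net)
    ei = expected_influence(net)
    harm = nx.harmonic_centrality(g, distance="distance")
    closeness = np.array([harm[n] for n in net.nodes])
    btw = nx.betweenness_centrality(g, weight="distance", normalized=False)
    betweenness = np.array([btw[n] for n in net.nodes])
    tab = pd.DataFrame(
        {
            "strength": strength,
            "expected_influence": ei,
            "closeness": closeness,
            "betweenness": betweenness,
        },
        index=pd.Index(net.nodes, name="node"),
    )
    for col in list(tab.columns):
        tab[f"z_{col}"] = _zscore(tab[col].to_numpy())
    if data is not None:
        tab["predictability"] = predictability(data, net.nodes)
    return tab


def centrality_long(tab: pd.DataFrame) -> pd.DataFrame:
    """Tidy (node, index, raw, z) version of a centrality table."""
    rows = []
    for idx in ("strength", "expected_influence", "closeness", "betweenness"):
        for node in tab.index:
            rows.append(
                {
                    "node": node,
                    "index": idx,
                    "raw": tab.loc[node, idx],
                    "z": tab.loc[node, f"z_{idx}"],
                }
            )
    return pd.DataFrame(rows)


# -- flow decomposition ------------------------------------------------

@dataclass
class FlowDecomposition:
    """Focal-node view of the network: which symptoms reach the focal node
    directly and which only through intermediaries."""

    focal: str
    direct: list[str]
    indirect_layers: list[list[str]]
    unreached: list[str]
    edges_to_focal: list[tuple[str, float]]

    def to_dict(self) -> dict:
        return {
            "focal": self.focal,
            "direct": self.direct,
            "indirect_layers": self.indirect_layers,
            "unreached": self.unreached,
            "edges_to_focal": [[n, float(w)] for n, w in self.edges_to_focal],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


def flow_decompose(net: NetworkModel, focal: str) -> FlowDecomposition:
    """Breadth-first partition of non-focal nodes around ``focal``.

    Layer 1 (direct) holds nodes with a nonzero edge to the focal node;
    layer k holds nodes first reached at distance k through nonzero edges;
    nodes with no path to the focal node are collected as unreached.
    ``edges_to_focal`` ranks the direct connections by |weight|.
    """
    if focal not in net.nodes:
        raise KeyError(f"unknown focal node {focal!r}")
    fi = net.nodes.index(focal)
    adj = net.weights != 0.0
    direct_idx = sorted(np.flatnonzero(adj[fi]))
    seen = {fi, *direct_idx}
    layers = [list(direct_idx)]
    frontier = list(direct_idx)
    while frontier:
        nxt = []
        for i in frontier:
            for j in np.flatnonzero(adj[i]):
                if j not in seen:
                    seen.add(int(j))
                    nxt.append(int(j))
        if nxt:
            layers.append(sorted(nxt))
        frontier = nxt
    unreached = [i for i in range(net.p) if i not in seen]
    edges = sorted(
        ((net.nodes[i], float(net.weights[fi, i])) for i in direct_idx),
        key=lambda t: -abs(t[1]),
    )
    names = lambda ix: [net.nodes[i] for i in ix]
    return FlowDecomposition(
        focal,
        names(layers[0]),
        [names(layer) for layer in layers[1:]],
        names(unreached),
        edges,
    )
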