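"""Shared builders for small hand-constructed networks and models."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from netrepurpose.ppi_network import DiseaseNetwork


def make_net(edges, dps=(), extra_nodes=()):
    """DiseaseNetwork from (u, v, weight) triples plus optional isolated nodes."""
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=float(w))
    g.add_nodes_from(extra_nodes)
    g.add_nodes_from(dps)
    return DiseaseNetwork(graph=g, dp_set=frozenset(dps))


def random_connected_net(n, p, seed, weight_range=(0.71, 1.0)):
    """Random connected weighted graph for oracle comparisons."""
    rng = np.random.default_rng(seed)
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if n < 2 or nx.is_connected(g):
            break
    g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
    for u, v in g.edges:
        g.edges[u, v]["weight"] = float(rng.uniform(*weight_range))
    return DiseaseNetwork(graph=g, dp_set=frozenset())


@pytest.fixture
def path_net():
    """Unweighted path A–B–C (weights 1)."""
    return make_net([("A", "B", 1.0), ("B", "C", 1.0)])


@pytest.fixture
def star_net():
    """Star K1,3 with center S."""
    return make_net([("S", "L1", 1.0), ("S", "L2", 1.0), ("S", "L3", 1.0)])
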