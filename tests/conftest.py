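"""Shared fixtures: small deterministic networks and the worked toy map."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from modmap import ModuleMap, Network


@pytest.fixture
def toy_instance():
    """Three-clique toy: H has cliques of sizes 3, 4 and 6; G links 1-2
    with 8 of 12 cross edges and 2-3 with 10 of 24 cross edges.

    Internal H scores are 3, 6 and 15; cross G-weights are +4 (8 edges,
    4 non-edges) and -4 (10 edges, 14 non-edges).
    """
    m1 = [f"a{i}" for i in range(1, 4)]
    m2 = [f"b{i}" for i in range(1, 5)]
    m3 = [f"c{i}" for i in range(1, 7)]
    nodes = m1 + m2 + m3
    h_edges = []
    for mod in (m1, m2, m3):
        h_edges.extend(itertools.combinations(mod, 2))
    h = Network.from_edges(h_edges, nodes=nodes)
    cross_12 = list(itertools.product(m1, m2))           # 12 pairs
    cross_23 = list(itertools.product(m2, m3))           # 24 pairs
    g_edges = cross_12[:8] + cross_23[:10]
    g = Network.from_edges(g_edges, nodes=nodes)
    return h, g, (frozenset(m1), frozenset(m2), frozenset(m3))


@pytest.fixture
def toy_two_module_map(toy_instance):
    _, _, (m1, m2, _) = toy_instance
    return ModuleMap([m1, m2], {(0, 1): __import__("modmap").MapLink(1e-3, 4.0)})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def er_network(n: int, p: float, seed: int) -> Network:
    """Seeded Erdős–Rényi graph on n nodes."""
    rng = np.random.default_rng(seed)
    a = np.triu(rng.random((n, n)) < p, 1)
    nodes = [f"v{i:03d}" for i in range(n)]
    edges = [(nodes[i], nodes[j]) for i, j in zip(*np.nonzero(a))]
    return Network.from_edges(edges, nodes=nodes)
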