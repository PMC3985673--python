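"""Initiator behaviour: biclique enumeration, cleaning and seeding."""

import itertools

import numpy as np
import pytest

from modmap import (
    Biclique,
    Network,
    SimConfig,
    dicer_clean,
    dicer_k_init,
    enumerate_maximal_bicliques,
    greedy_init,
    hclust_init,
    mbc_dicer_init,
    pair_jaccard,
    simulate,
)
from conftest import er_network


def brute_force_bicliques(net, min_side):
    """Subset-pair oracle: all maximal bicliques via closure of every subset."""
    nodes = net.nodes
    a = net.adjacency_matrix()

    def common(idx):
        mask = np.ones(len(nodes), bool)
        for i in idx:
            mask &= a[i]
        return frozenset(np.flatnonzero(mask).tolist())

    found = set()
    for r in range(1, len(nodes) + 1):
        for sub in itertools.combinations(range(len(nodes)), r):
            b_side = common(sub)
            if not b_side:
                continue
            a_side = common(sorted(b_side))
            if set(sub) <= a_side:
                b_closed = common(sorted(a_side))
                if len(a_side) >= min_side and len(b_closed) >= min_side:
                    found.add(frozenset((
                        frozenset(nodes[i] for i in a_side),
                        frozenset(nodes[i] for i in b_closed),
                    )))
    return found


class TestEnumeration:
    def test_single_edge(self):
        res = enumerate_maximal_bicliques(Network.from_edges([("a", "b")]), min_side=1)
        assert [(sorted(b.side_a), sorted(b.side_b)) for b in res.bicliques] == [
            (["a"], ["b"])]

    def test_path_has_unique_maximal_biclique(self):
        net = Network.from_edges([("a", "b"), ("b", "c")])
        res = enumerate_maximal_bicliques(net, min_side=1)
        assert len(res.bicliques) == 1
        bic = res.bicliques[0]
        assert {bic.side_a, bic.side_b} == {frozenset("b"), frozenset("ac")}

    def test_four_cycle(self):
        net = Network.from_edges([("a", "b"), ("b", "c"), ("c", "d"), ("a", "d")])
        res = enumerate_maximal_bicliques(net, min_side=2)
        assert len(res.bicliques) == 1
        bic = res.bicliques[0]
        assert {bic.side_a, bic.side_b} == {frozenset("ac"), frozenset("bd")}

    @pytest.mark.parametrize("seed,min_side", [(s, m) for s in range(8) for m in (1, 2, 3)])
    def test_matches_subset_pair_oracle(self, seed, min_side):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        net = er_network(n, float(rng.uniform(0.2, 0.7)), seed + 100)
        res = enumerate_maximal_bicliques(net, min_side=min_side)
        mine = {frozenset((b.side_a, b.side_b)) for b in res.bicliques}
        assert mine == brute_force_bicliques(net, min_side)
        assert not res.truncated

    def test_every_emitted_biclique_is_complete_and_maximal(self):
        net = er_network(12, 0.45, 77)
        res = enumerate_maximal_bicliques(net, min_side=2)
        for bic in res.bicliques:
            assert not (bic.side_a & bic.side_b)
            for u, v in itertools.product(bic.side_a, bic.side_b):
                assert net.has_edge(u, v)
            for w in set(net.nodes) - bic.side_a - bic.side_b:
                assert not bic.side_b <= net.neighbors(w)  # cannot extend side A
                assert not bic.side_a <= net.neighbors(w)  # cannot extend side B

    def test_truncation_flagged(self):
        net = er_network(30, 0.5, 9)
        res = enumerate_maximal_bicliques(net, min_side=1, max_results=5)
        assert res.truncated and len(res.bicliques) <= 5

    def test_deterministic(self):
        net = er_network(15, 0.4, 11)
        a = enumerate_maximal_bicliques(net, min_side=2)
        b = enumerate_maximal_bicliques(net, min_side=2)
        assert a.bicliques == b.bicliques


class TestDicerClean:
    def test_clique_sides_unchanged(self):
        m1, m2 = ["a1", "a2", "a3"], ["b1", "b2", "b3"]
        h = Network.from_edges(
            list(itertools.combinations(m1, 2)) + list(itertools.combinations(m2, 2)))
        g = Network.from_edges(itertools.product(m1, m2))
        cp = dicer_clean(h, g, Biclique(frozenset(m1), frozenset(m2)), min_size=3)
        assert cp is not None
        assert {cp.side_a, cp.side_b} == {frozenset(m1), frozenset(m2)}
        assert 0 < cp.p_value <= 1

    def test_isolated_node_removed(self):
        m1 = ["a1", "a2", "a3", "loner"]
        m2 = ["b1", "b2", "b3"]
        h_edges = [e for e in itertools.combinations(m1, 2) if "loner" not in e]
        h_edges += list(itertools.combinations(m2, 2))
        h = Network.from_edges(h_edges, nodes=m1 + m2)
        g = Network.from_edges(itertools.product(m1, m2))
        cp = dicer_clean(h, g, Biclique(frozenset(m1), frozenset(m2)), min_size=3)
        assert {cp.side_a, cp.side_b} == {frozenset(m1) - {"loner"}, frozenset(m2)}

    def test_rejected_when_side_shrinks_below_minimum(self):
        m1, m2 = ["a1", "a2", "a3", "weak"], ["b1", "b2", "b3"]
        h_edges = [e for e in itertools.combinations(m1, 2) if "weak" not in e]
        h_edges += list(itertools.combinations(m2, 2))
        h = Network.from_edges(h_edges, nodes=m1 + m2)
        g = Network.from_edges(itertools.product(m1, m2))
        assert dicer_clean(h, g, Biclique(frozenset(m1), frozenset(m2)), min_size=4) is None


class TestMbcDicer:
    def test_noiseless_planted_map_recovered_exactly(self):
        h, g, truth = simulate(SimConfig(n_nodes=200, n_modules=3, seed=5))
        init = mbc_dicer_init(h, g, min_size=5)
        assert pair_jaccard(init.sets, truth.modules) == 1.0
        # first-come claiming may leave later tree links without both sides,
        # but at least one seed link must be proposed
        assert len(init.seed_links) >= 1

    def test_empty_g_gives_empty_solution(self):
        h = Network.from_edges([("a", "b")], nodes=["a", "b", "c"])
        g = Network(["a", "b", "c"])
        init = mbc_dicer_init(h, g, min_size=2)
        assert init.sets == [] and init.seed_links == []

    def test_overlapping_pairs_resolved_first_come(self):
        # two linked module pairs sharing one module: the shared module is
        # claimed once and the later pair keeps only its unclaimed side
        mods = {
            "A": [f"a{i}" for i in range(5)],
            "B": [f"b{i}" for i in range(6)],
            "C": [f"c{i}" for i in range(5)],
        }
        h_edges = [e for m in mods.values() for e in itertools.combinations(m, 2)]
        g_edges = list(itertools.product(mods["A"], mods["B"]))
        g_edges += list(itertools.product(mods["B"], mods["C"]))
        nodes = sum(mods.values(), [])
        h = Network.from_edges(h_edges, nodes=nodes)
        g = Network.from_edges(g_edges, nodes=nodes)
        init = mbc_dicer_init(h, g, min_size=5)
        assert sorted(map(sorted, init.sets)) == sorted(
            map(sorted, [mods["A"], mods["B"], mods["C"]]))
        # all sets disjoint
        seen = set()
        for s in init.sets:
            assert not (seen & s)
            seen |= s

    def test_deterministic(self):
        h, g, _ = simulate(SimConfig(n_nodes=150, n_modules=3, flip_p=0.05, seed=6))
        a = mbc_dicer_init(h, g, min_size=5)
        b = mbc_dicer_init(h, g, min_size=5)
        assert a.sets == b.sets and a.seed_links == b.seed_links


class TestDicerK:
    def test_noiseless_planted_pair_recovered(self):
        # one linked pair: recovered exactly (node claiming prevents a module
        # shared by two tree links from seeding twice, so use two modules)
        h, g, truth = simulate(SimConfig(n_nodes=200, n_modules=2, seed=7))
        init = dicer_k_init(h, g, k=5)
        assert pair_jaccard(init.sets, truth.modules) == 1.0
        assert len(init.seed_links) == 1

    def test_small_bicliques_filtered_by_k(self):
        m1, m2 = ["a1", "a2", "a3"], ["b1", "b2", "b3"]
        h = Network.from_edges(
            list(itertools.combinations(m1, 2)) + list(itertools.combinations(m2, 2)))
        g = Network.from_edges(itertools.product(m1, m2))
        assert dicer_k_init(h, g, k=5).sets == []

    def test_two_cliques_with_biclique_link_k2(self):
        m1, m2 = ["a1", "a2", "a3", "a4"], ["b1", "b2", "b3", "b4"]
        h = Network.from_edges(
            list(itertools.combinations(m1, 2)) + list(itertools.combinations(m2, 2)))
        g = Network.from_edges(itertools.product(m1, m2))
        init = dicer_k_init(h, g, k=2)
        assert sorted(map(sorted, init.sets)) == [sorted(m1), sorted(m2)]
        assert len(init.seed_links) == 1


class TestHclust:
    def test_two_disjoint_cliques(self):
        m1 = [f"a{i}" for i in range(10)]
        m2 = [f"b{i}" for i in range(10)]
        h = Network.from_edges(
            list(itertools.combinations(m1, 2)) + list(itertools.combinations(m2, 2)))
        init = hclust_init(h, min_size=5, max_size=15)
        assert sorted(map(sorted, init.sets)) == [sorted(m1), sorted(m2)]
        assert init.seed_links == []

    def test_single_clique_within_band(self):
        m = [f"a{i}" for i in range(12)]
        h = Network.from_edges(itertools.combinations(m, 2))
        init = hclust_init(h, min_size=5, max_size=20)
        assert sorted(map(sorted, init.sets)) == [sorted(m)]

    @pytest.mark.parametrize("seed", range(10))
    def test_noisy_two_block_recovery(self, seed):
        rng = np.random.default_rng(seed)
        m1 = [f"a{i}" for i in range(10)]
        m2 = [f"b{i}" for i in range(10)]
        nodes = m1 + m2
        edges = []
        for u, v in itertools.combinations(nodes, 2):
            inside = (u[0] == v[0])
            if inside != (rng.random() < 0.1):  # flip with P = 0.1
                edges.append((u, v))
        h = Network.from_edges(edges, nodes=nodes)
        init = hclust_init(h, min_size=5, max_size=15)
        assert pair_jaccard(init.sets, [frozenset(m1), frozenset(m2)]) >= 0.9


class TestGreedy:
    def test_six_clique_recovered(self):
        m = [f"a{i}" for i in range(6)]
        nodes = m + ["x", "y", "z"]
        h = Network.from_edges(itertools.combinations(m, 2), nodes=nodes)
        init = greedy_init(h, min_size=5)
        assert sorted(map(sorted, init.sets)) == [sorted(m)]

    def test_all_negative_weights_yield_nothing(self):
        rows = [(u, v, -1.0) for u, v in itertools.combinations("abcdef", 2)]
        h = Network.from_edges(rows, mode="weighted")
        assert greedy_init(h, min_size=2).sets == []

    def test_first_seed_claims_shared_nodes(self):
        # two overlapping near-cliques sharing three nodes
        shared = ["s1", "s2", "s3"]
        left = ["l1", "l2", "l3"] + shared
        right = ["r1", "r2", "r3"] + shared
        edges = set(itertools.combinations(sorted(left), 2)) | set(
            itertools.combinations(sorted(right), 2))
        h = Network.from_edges(sorted(edges))
        init = greedy_init(h, min_size=3)
        claimed = set()
        for s in init.sets:
            assert not (claimed & s)
            claimed |= s
        assert any(set(shared) <= s for s in init.sets)
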