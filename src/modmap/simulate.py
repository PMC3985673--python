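"""Planted module-map simulator.

Generates matched network pairs (H, G) containing a perfect planted
module map — modules are cliques in H, map links are complete bipartite
subgraphs in G, and the map topology is a uniform random labelled tree —
plus decoy cliques (H) and decoy bicliques (G) that do not belong to the
map.  All planted structures use pairwise-disjoint node sets with sizes
drawn uniformly from a configured range.  Noise is then applied: in
unweighted mode every node pair is flipped independently with
probability P; in weighted mode every pair receives a Gaussian weight
centred at +1 (planted pair) or -1 (background pair) with standard
deviation sigma.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .graph_core import ConfigError, DomainError, Network, UNWEIGHTED, WEIGHTED

logger = logging.getLogger("modmap")


@dataclass
class SimConfig:
    """Study conditions for one simulated instance.

    Defaults follow the 500-node benchmark setting: six modules linked
    in a random tree, two decoy cliques and two decoy bicliques, all
    structure sizes uniform in 10..20.
    """

    n_nodes: int = 500
    n_modules: int = 6
    n_clique_decoys: int = 2
    n_biclique_decoys: int = 2
    size_range: tuple[int, int] = (10, 20)
    mode: str = UNWEIGHTED
    flip_p: float = 0.0
    sigma: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.size_range
        if lo < 2 or hi < lo:
            raise ConfigError(f"bad size range {self.size_range}")
        if not (0.0 <= self.flip_p <= 1.0):
            raise ConfigError("flip probability must be in [0, 1]")
        if self.sigma < 0.0:
            raise ConfigError("sigma must be >= 0")
        if self.mode not in (UNWEIGHTED, WEIGHTED):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.n_modules < 2:
            raise ConfigError("need at least two modules to form a tree")
        least = (self.n_modules + self.n_clique_decoys + 2 * self.n_biclique_decoys) * lo
        if least > self.n_nodes:
            raise ConfigError(
                f"planted structures need at least {least} nodes but only "
                f"{self.n_nodes} are available"
            )


@dataclass
class PlantedTruth:
    """Ground truth of one simulated instance."""

    modules: list[frozenset]
    tree_links: list[tuple[int, int]]
    clique_decoys: list[frozenset] = field(default_factory=list)
    biclique_decoys: list[tuple[frozenset, frozenset]] = field(default_factory=list)


def random_tree(m: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Uniform random labelled tree on m labels via a Prüfer sequence."""
    if m < 2:
        raise DomainError("a tree needs at least two labels")
    if m == 2:
        return [(0, 1)]
    prufer = rng.integers(0, m, size=m - 2)
    degree = np.ones(m, dtype=int)
    for x in prufer:
        degree[x] += 1
    edges = []
    leaves = sorted(i for i in range(m) if degree[i] == 1)
    for x in prufer:
        leaf = leaves.pop(0)
        edges.append((min(leaf, int(x)), max(leaf, int(x))))
        degree[x] -= 1
        if degree[x] == 1:
            # keep the leaf pool sorted for determinism
            import bisect

            bisect.insort(leaves, int(x))
    u, v = leaves
    edges.append((min(u, v), max(u, v)))
    return edges


def _node_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"n{i + 1:0{width}d}" for i in range(n)]


def plant_map(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[Network, Network, PlantedTruth]:
    """Noiseless planted instance: H* (cliques) and G* (link bicliques)."""
    cfg.validate()
    lo, hi = cfg.size_range
    nodes = _node_ids(cfg.n_nodes)
    sizes_mod = rng.integers(lo, hi + 1, size=cfg.n_modules)
    sizes_cd = rng.integers(lo, hi + 1, size=cfg.n_clique_decoys)
    sizes_bd = rng.integers(lo, hi + 1, size=(cfg.n_biclique_decoys, 2))
    total = int(sizes_mod.sum() + sizes_cd.sum() + sizes_bd.sum())
    if total > cfg.n_nodes:
        raise ConfigError(
            f"drawn structure sizes need {total} nodes, only {cfg.n_nodes} available"
        )
    cursor = 0

    def take(k: int) -> frozenset:
        nonlocal cursor
        s = frozenset(nodes[cursor: cursor + k])
        cursor += k
        return s

    modules = [take(int(k)) for k in sizes_mod]
    clique_decoys = [take(int(k)) for k in sizes_cd]
    biclique_decoys = [(take(int(a)), take(int(b))) for a, b in sizes_bd]
    tree = random_tree(cfg.n_modules, rng)

    h_edges = []
    for s in modules + clique_decoys:
        mem = sorted(s)
        for i in range(len(mem)):
            for j in range(i + 1, len(mem)):
                h_edges.append((mem[i], mem[j]))
    g_edges = []
    for (i, j) in tree:
        for u in sorted(modules[i]):
            for v in sorted(modules[j]):
                g_edges.append((u, v))
    for (a, b) in biclique_decoys:
        for u in sorted(a):
            for v in sorted(b):
                g_edges.append((u, v))

    h_star = Network.from_edges(h_edges, mode=UNWEIGHTED, nodes=nodes)
    g_star = Network.from_edges(g_edges, mode=UNWEIGHTED, nodes=nodes)
    truth = PlantedTruth(modules, tree, clique_decoys, biclique_decoys)
    return h_star, g_star, truth


def apply_noise(
    h_star: Network,
    g_star: Network,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[Network, Network]:
    """Noisy copies of the planted pair.

    Unweighted: every node pair flips independently with probability P.
    Weighted: every pair's weight is drawn from N(+1, sigma) when the
    pair is planted and N(-1, sigma) otherwise.
    """
    out = []
    for star in (h_star, g_star):
        n = star.n
        a = star.adjacency_matrix()
        iu = np.triu_indices(n, 1)
        if cfg.mode == UNWEIGHTED:
            flips = rng.random(len(iu[0])) < cfg.flip_p
            vals = a[iu] ^ flips
            net = Network(star.nodes, mode=UNWEIGHTED)
            for i, j in zip(iu[0][vals], iu[1][vals]):
                u, v = star.nodes[i], star.nodes[j]
                net._adj[u].add(v)
                net._adj[v].add(u)
            out.append(net)
        else:
            centers = np.where(a[iu], 1.0, -1.0)
            vals = centers + cfg.sigma * rng.standard_normal(len(centers))
            net = Network(star.nodes, mode=WEIGHTED)
            W = np.zeros((n, n))
            W[iu] = vals
            W += W.T
            net._W = W
            out.append(net)
    return out[0], out[1]


def simulate(cfg: SimConfig) -> tuple[Network, Network, PlantedTruth]:
    """Full pipeline: plant a map, apply noise; deterministic given cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    h_star, g_star, truth = plant_map(cfg, rng)
    h, g = apply_noise(h_star, g_star, cfg, rng)
    return h, g, truth


# -- truth/instance serialisation ------------------------------------


def write_truth(truth: PlantedTruth, path: str | Path) -> None:
    """Tab-separated truth file: one row per planted set plus tree edges."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("type\tindex\tnodes\n")
        for i, m in enumerate(truth.modules):
            fh.write(f"module\t{i}\t{','.join(sorted(m))}\n")
        for i, c in enumerate(truth.clique_decoys):
            fh.write(f"clique\t{i}\t{','.join(sorted(c))}\n")
        for i, (a, b) in enumerate(truth.biclique_decoys):
            fh.write(f"bicliqueA\t{i}\t{','.join(sorted(a))}\n")
            fh.write(f"bicliqueB\t{i}\t{','.join(sorted(b))}\n")
        for (i, j) in truth.tree_links:
            fh.write(f"tree_edge\t{i}\t{j}\n")


def read_truth(path: str | Path) -> PlantedTruth:
    modules: dict[int, frozenset] = {}
    cliques: dict[int, frozenset] = {}
    bic_a: dict[int, frozenset] = {}
    bic_b: dict[int, frozenset] = {}
    tree: list[tuple[int, int]] = []
    with Path(path).open() as fh:
        header = fh.readline()
        for line in fh:
            kind, idx, payload = line.rstrip("\n").split("\t")
            if kind == "tree_edge":
                tree.append((int(idx), int(payload)))
                continue
            members = frozenset(payload.split(","))
            {"module": modules, "clique": cliques, "bicliqueA": bic_a, "bicliqueB": bic_b}[
                kind
            ][int(idx)] = members
    return PlantedTruth(
        [modules[i] for i in sorted(modules)],
        tree,
        [cliques[i] for i in sorted(cliques)],
        [(bic_a[i], bic_b[i]) for i in sorted(bic_a)],
    )
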