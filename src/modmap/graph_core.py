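"""Two-network data model and module-map score arithmetic.

A module map summarises a pair of networks H and G defined over the same
gene universe.  Modules are disjoint node sets that are heavy inside H
(e.g. protein complexes in a PPI network), and links are module pairs
that are heavy in G (e.g. dense genetic-interaction bundles between two
complexes).  Unweighted networks follow the signed convention used
throughout: an edge weighs +1 and a missing pair weighs -1, so dense
structures score high and sparse ones negative.  Weighted networks carry
a real weight for every node pair.

The global score of a map is the sum of H-weights inside each module
plus the sum of G-weights across every linked module pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

logger = logging.getLogger("modmap")

UNWEIGHTED = "unweighted"
WEIGHTED = "weighted"


class ModMapError(Exception):
    """Base class for errors raised by this package."""


class UnknownNodeError(ModMapError, KeyError):
    """A node identifier is not part of the network."""


class DomainError(ModMapError, ValueError):
    """Arguments violate a precondition (self-pairs, overlapping sets, ...)."""


class ConfigError(ModMapError, ValueError):
    """Invalid configuration (thresholds, sizes, modes)."""


class Network:
    """A symmetric signed-weight relation over a node universe.

    Parameters
    ----------
    nodes
        Node identifiers (strings).  Stored sorted; duplicates collapse.
    mode
        ``"unweighted"`` (edges present/absent, implied weights +1/-1) or
        ``"weighted"`` (every pair carries a real weight; pairs never
        assigned a weight default to -1, matching the non-edge
        convention).
    """

    __slots__ = ("mode", "nodes", "_idx", "_adj", "_W", "_cache")

    def __init__(self, nodes: Iterable[str], mode: str = UNWEIGHTED):
        if mode not in (UNWEIGHTED, WEIGHTED):
            raise ConfigError(f"unknown network mode {mode!r}")
        self.mode = mode
        self.nodes: tuple[str, ...] = tuple(sorted(set(nodes)))
        self._idx = {u: i for i, u in enumerate(self.nodes)}
        n = len(self.nodes)
        self._cache: dict = {}
        if mode == UNWEIGHTED:
            self._adj: dict[str, set[str]] = {u: set() for u in self.nodes}
            self._W = None
        else:
            self._adj = None
            W = np.full((n, n), -1.0)
            np.fill_diagonal(W, 0.0)
            self._W = W

    # -- construction ------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        rows: Iterable[tuple],
        mode: str = UNWEIGHTED,
        nodes: Optional[Iterable[str]] = None,
    ) -> "Network":
        """Build a network from ``(u, v)`` or ``(u, v, w)`` rows.

        Self-loops are dropped with a warning.  Duplicate rows collapse
        to one; for weighted input the last weight wins (warning logged).
        """
        rows = list(rows)
        if nodes is None:
            universe = set()
            for r in rows:
                universe.add(str(r[0]))
                universe.add(str(r[1]))
            nodes = universe
        net = cls(nodes, mode=mode)
        seen: set[frozenset] = set()
        n_self = n_dup = 0
        for r in rows:
            u, v = str(r[0]), str(r[1])
            if u == v:
                n_self += 1
                continue
            if u not in net._idx:
                raise UnknownNodeError(u)
            if v not in net._idx:
                raise UnknownNodeError(v)
            key = frozenset((u, v))
            if key in seen:
                n_dup += 1
            seen.add(key)
            if mode == UNWEIGHTED:
                net._adj[u].add(v)
                net._adj[v].add(u)
            else:
                if len(r) < 3:
                    raise ConfigError("weighted mode requires a weight per row")
                w = float(r[2])
                i, j = net._idx[u], net._idx[v]
                net._W[i, j] = w
                net._W[j, i] = w
        if n_self:
            logger.warning("dropped %d self-loop row(s)", n_self)
        if n_dup:
            logger.warning("collapsed %d duplicate edge row(s) (last weight wins)", n_dup)
        return net

    # -- basic queries -----------------------------------------------

    @property
    def n(self) -> int:
        return len(self.nodes)

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, u: str) -> bool:
        return u in self._idx

    def index(self, u: str) -> int:
        try:
            return self._idx[u]
        except KeyError:
            raise UnknownNodeError(u) from None

    def indices(self, us: Iterable[str]) -> np.ndarray:
        return np.array([self.index(u) for u in us], dtype=np.intp)

    def has_edge(self, u: str, v: str) -> bool:
        """Positive-weight pair test (edge in unweighted mode, w > 0 in weighted)."""
        return self.signed_weight(u, v) > 0

    def neighbors(self, u: str) -> set[str]:
        if self.mode == UNWEIGHTED:
            if u not in self._adj:
                raise UnknownNodeError(u)
            return set(self._adj[u])
        i = self.index(u)
        return {self.nodes[j] for j in np.flatnonzero(self._W[i] > 0)}

    def degree(self, u: str) -> int:
        return len(self.neighbors(u))

    def edges(self) -> Iterator[tuple]:
        """Yield each positive pair once (``(u, v)`` or ``(u, v, w)``)."""
        if self.mode == UNWEIGHTED:
            for u in self.nodes:
                for v in sorted(self._adj[u]):
                    if u < v:
                        yield (u, v)
        else:
            n = self.n
            for i in range(n):
                for j in range(i + 1, n):
                    if self._W[i, j] > 0:
                        yield (self.nodes[i], self.nodes[j], float(self._W[i, j]))

    def signed_weight(self, u: str, v: str) -> float:
        """Signed weight of a pair: +1/-1 in unweighted mode, stored weight otherwise."""
        if u == v:
            raise DomainError(f"self-pair ({u!r}, {u!r}) has no weight")
        if self.mode == UNWEIGHTED:
            if u not in self._adj:
                raise UnknownNodeError(u)
            if v not in self._adj:
                raise UnknownNodeError(v)
            return 1.0 if v in self._adj[u] else -1.0
        return float(self._W[self.index(u), self.index(v)])

    # -- dense views (cached) ----------------------------------------

    def weight_matrix(self) -> np.ndarray:
        """Dense symmetric signed-weight matrix with zero diagonal."""
        W = self._cache.get("W")
        if W is None:
            if self.mode == WEIGHTED:
                W = self._W
            else:
                A = self.adjacency_matrix()
                W = np.where(A, 1.0, -1.0)
                np.fill_diagonal(W, 0.0)
                self._cache["W"] = W
        return W

    def adjacency_matrix(self, threshold: float = 0.0) -> np.ndarray:
        """Boolean matrix of pairs with weight strictly above ``threshold``."""
        key = ("A", threshold)
        A = self._cache.get(key)
        if A is None:
            n = self.n
            if self.mode == UNWEIGHTED:
                A = np.zeros((n, n), dtype=bool)
                for u, nbrs in self._adj.items():
                    i = self._idx[u]
                    for v in nbrs:
                        A[i, self._idx[v]] = True
            else:
                A = self._W > threshold
                np.fill_diagonal(A, False)
            self._cache[key] = A
        return A

    def binarize(self, threshold: float = 0.0) -> "Network":
        """Unweighted view keeping pairs with weight > ``threshold`` as edges."""
        if self.mode == UNWEIGHTED and threshold == 0.0:
            return self
        net = Network(self.nodes, mode=UNWEIGHTED)
        A = self.adjacency_matrix(threshold)
        for i, j in zip(*np.nonzero(np.triu(A, 1))):
            u, v = self.nodes[i], self.nodes[j]
            net._adj[u].add(v)
            net._adj[v].add(u)
        return net

    def restrict(self, keep: Iterable[str]) -> "Network":
        """Induced sub-network on ``keep`` (intersection with current nodes)."""
        keep = sorted(set(keep) & set(self.nodes))
        net = Network(keep, mode=self.mode)
        if self.mode == UNWEIGHTED:
            ks = set(keep)
            for u in keep:
                net._adj[u] = self._adj[u] & ks
        else:
            idx = self.indices(keep)
            net._W = self._W[np.ix_(idx, idx)].copy()
        return net


def align(h: Network, g: Network) -> tuple[Network, Network]:
    """Restrict H and G to their shared node universe, logging dropped counts."""
    shared = set(h.nodes) & set(g.nodes)
    dh = h.n - len(shared)
    dg = g.n - len(shared)
    if dh or dg:
        logger.info(
            "restricting to %d shared nodes (dropped %d from H, %d from G)",
            len(shared), dh, dg,
        )
        return h.restrict(shared), g.restrict(shared)
    return h, g


# -- module map ------------------------------------------------------


@dataclass(frozen=True)
class MapLink:
    """A map link: combined p-value and total G-weight across the pair."""

    p_value: float
    weight: float


@dataclass
class ModuleMap:
    """Disjoint modules plus links between module-index pairs (i < j)."""

    modules: list[frozenset] = field(default_factory=list)
    links: dict[tuple[int, int], MapLink] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.modules = [frozenset(m) for m in self.modules]
        seen: set = set()
        for m in self.modules:
            if seen & m:
                raise DomainError("modules must be pairwise disjoint")
            seen |= m
        for (i, j) in self.links:
            if not (0 <= i < j < len(self.modules)):
                raise DomainError(f"bad link index pair ({i}, {j})")

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    @property
    def genes_covered(self) -> int:
        return sum(len(m) for m in self.modules)

    @property
    def max_module_size(self) -> int:
        return max((len(m) for m in self.modules), default=0)

    def linked_indices(self, i: int) -> set[int]:
        out = set()
        for (a, b) in self.links:
            if a == i:
                out.add(b)
            elif b == i:
                out.add(a)
        return out


# -- score arithmetic ------------------------------------------------


def signed_weight(net: Network, u: str, v: str) -> float:
    """Signed weight of the pair ``(u, v)`` in ``net``."""
    return net.signed_weight(u, v)


def module_internal_score(h: Network, members: Iterable[str]) -> float:
    """Sum of signed H-weights over all unordered pairs inside a module.

    Zero for modules of size <= 1.
    """
    idx = h.indices(members)
    if len(set(idx)) != len(idx):
        raise DomainError("duplicate nodes in module")
    if len(idx) <= 1:
        return 0.0
    W = h.weight_matrix()
    return float(W[np.ix_(idx, idx)].sum() / 2.0)


def link_weight(g: Network, left: Iterable[str], right: Iterable[str]) -> float:
    """Sum of signed G-weights over all cross pairs between two disjoint sets."""
    left, right = set(left), set(right)
    if not left or not right:
        raise DomainError("link sides must be non-empty")
    if left & right:
        raise DomainError("link sides must be disjoint")
    li = g.indices(left)
    ri = g.indices(right)
    W = g.weight_matrix()
    return float(W[np.ix_(li, ri)].sum())


def global_score(h: Network, g: Network, mmap: ModuleMap) -> float:
    """Total map score: internal H-weight of modules plus G-weight of links."""
    score = 0.0
    for m in mmap.modules:
        score += module_internal_score(h, m)
    for (i, j) in mmap.links:
        score += link_weight(g, mmap.modules[i], mmap.modules[j])
    return score
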