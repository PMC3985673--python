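"""Initiators: first-phase algorithms producing disjoint seed modules.

Four seeding strategies are provided:

* ``mbc_dicer_init`` — enumerate maximal (non-induced) bicliques of the
  unweighted view G', clean each side against H, rank and greedily
  assemble disjoint linked seed pairs (the MBC-DICER initiator);
* ``dicer_k_init`` — grow one linked module pair at a time from single
  G'-edges, keeping pairs with both sides of size >= k;
* ``hclust_init`` — average-linkage hierarchical clustering of H with a
  largest-first recursive tree cut;
* ``greedy_init`` — greedy node addition around heavy H-edges.

All initiators are deterministic given their inputs and return pairwise
disjoint node sets; MBC-DICER and DICER_k also propose seed links.

Maximal bicliques are enumerated through the Galois correspondence: for
a node set S, f(S) is the common neighbourhood of S, and the maximal
bicliques are exactly the pairs (A, f(A)) with A closed under
f(f(.)).  Closed sets are enumerated once each by prefix-preserving
closure extension, with monotone pruning on the minimum side size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numba
import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .graph_core import ConfigError, DomainError, Network, UNWEIGHTED
from .link_stats import (
    HYPERGEOM_FISHER,
    TestCounter,
    link_pvalue,
)

logger = logging.getLogger("modmap")

DEFAULT_MAX_RESULTS = 10 ** 6


@dataclass(frozen=True)
class Biclique:
    """A maximal biclique: every cross pair between the sides is an edge."""

    side_a: frozenset
    side_b: frozenset


@dataclass
class BicliqueEnumeration:
    bicliques: list[Biclique]
    truncated: bool = False
    n_explored: int = 0


@dataclass
class InitialSolution:
    """Disjoint seed sets plus optional seed links (index pairs into sets)."""

    sets: list[frozenset] = field(default_factory=list)
    seed_links: list[tuple[int, int]] = field(default_factory=list)
    seed_link_pvalues: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set = set()
        for s in self.sets:
            if seen & s:
                raise DomainError("seed sets must be pairwise disjoint")
            seen |= s


# -- maximal biclique enumeration ------------------------------------


@numba.njit(cache=True, inline="always")
def _pop64(x):
    x = x - ((x >> np.uint64(1)) & np.uint64(0x5555555555555555))
    x = (x & np.uint64(0x3333333333333333)) + (
        (x >> np.uint64(2)) & np.uint64(0x3333333333333333)
    )
    x = (x + (x >> np.uint64(4))) & np.uint64(0x0F0F0F0F0F0F0F0F)
    return (x * np.uint64(0x0101010101010101)) >> np.uint64(56)


@numba.njit(cache=True, inline="always")
def _ctz64(x):
    # trailing zero count of a non-zero word
    return _pop64((x & (~x + np.uint64(1))) - np.uint64(1))


@numba.njit(cache=True)
def _biclique_kernel(packed, n, min_side, max_results, max_explored):
    nw = packed.shape[1]
    one = np.uint64(1)
    full = np.zeros(nw, np.uint64)
    for i in range(n):
        full[i >> 6] |= one << np.uint64(i & 63)

    cap = 8192
    st_s = np.zeros((cap, nw), np.uint64)
    st_f = np.zeros((cap, nw), np.uint64)
    st_last = np.zeros(cap, np.int64)
    st_f[0] = full
    st_last[0] = -1
    sp = 1

    rcap = 4096
    res_s = np.zeros((rcap, nw), np.uint64)
    res_f = np.zeros((rcap, nw), np.uint64)
    nres = 0
    explored = 0
    truncated = False

    cnt = np.zeros(n, np.int64)
    stamp = np.zeros(n, np.int64)
    cur = 0
    new_f = np.zeros(nw, np.uint64)
    new_t = np.zeros(nw, np.uint64)

    while sp > 0:
        sp -= 1
        s_bits = st_s[sp].copy()
        f_bits = st_f[sp].copy()
        last = st_last[sp]
        explored += 1
        if explored > max_explored or nres >= max_results:
            truncated = True
            break
        sz_s = 0
        sz_f = 0
        for w in range(nw):
            sz_s += _pop64(s_bits[w])
            sz_f += _pop64(f_bits[w])
        if sz_s >= min_side and sz_f >= min_side:
            # sides are disjoint, so the smaller first member decides the
            # canonical orientation; emit each biclique exactly once
            min_s = -1
            min_f = -1
            for w in range(nw):
                if min_s < 0 and s_bits[w]:
                    min_s = (w << 6) + int(_ctz64(s_bits[w]))
                if min_f < 0 and f_bits[w]:
                    min_f = (w << 6) + int(_ctz64(f_bits[w]))
            if min_s < min_f:
                if nres == rcap:
                    rcap *= 2
                    tmp_s = np.zeros((rcap, nw), np.uint64)
                    tmp_f = np.zeros((rcap, nw), np.uint64)
                    tmp_s[:nres] = res_s
                    tmp_f[:nres] = res_f
                    res_s = tmp_s
                    res_f = tmp_f
                res_s[nres] = s_bits
                res_f[nres] = f_bits
                nres += 1
        # count, per node j, its neighbours inside f
        cur += 1
        for w in range(nw):
            bits = f_bits[w]
            while bits:
                m = (w << 6) + int(_ctz64(bits))
                bits &= bits - one
                row = packed[m]
                for w2 in range(nw):
                    rb = row[w2]
                    while rb:
                        j = (w2 << 6) + int(_ctz64(rb))
                        rb &= rb - one
                        if stamp[j] != cur:
                            stamp[j] = cur
                            cnt[j] = 1
                        else:
                            cnt[j] += 1
        # push children in descending j so lower indices are explored first
        for j in range(n - 1, last, -1):
            if stamp[j] != cur or cnt[j] < min_side:
                continue
            if (s_bits[j >> 6] >> np.uint64(j & 63)) & one:
                continue
            sz = 0
            row = packed[j]
            for w in range(nw):
                new_f[w] = f_bits[w] & row[w]
                sz += _pop64(new_f[w])
            if sz < min_side:
                continue
            # closure: nodes adjacent to the whole reduced neighbourhood
            for w in range(nw):
                new_t[w] = full[w]
            for w in range(nw):
                bits = new_f[w]
                while bits:
                    m = (w << 6) + int(_ctz64(bits))
                    bits &= bits - one
                    mr = packed[m]
                    for w2 in range(nw):
                        new_t[w2] &= mr[w2]
            # prefix-preserving test: the closure adds no member below j
            ok = True
            jw = j >> 6
            for w in range(jw + 1):
                below = ~np.uint64(0) if w < jw else (one << np.uint64(j & 63)) - one
                if (new_t[w] & below & ~s_bits[w]) != np.uint64(0):
                    ok = False
                    break
            if not ok:
                continue
            if sp == cap:
                cap *= 2
                tmp_s = np.zeros((cap, nw), np.uint64)
                tmp_f = np.zeros((cap, nw), np.uint64)
                tmp_l = np.zeros(cap, np.int64)
                tmp_s[:sp] = st_s
                tmp_f[:sp] = st_f
                tmp_l[:sp] = st_last
                st_s = tmp_s
                st_f = tmp_f
                st_last = tmp_l
            st_s[sp] = new_t
            st_f[sp] = new_f
            st_last[sp] = j
            sp += 1

    return res_s[:nres], res_f[:nres], truncated, explored


def _pack_bool(a: np.ndarray) -> np.ndarray:
    n = a.shape[1]
    pad = (-n) % 64
    if pad:
        a = np.concatenate([a, np.zeros((a.shape[0], pad), dtype=bool)], axis=1)
    pk = np.packbits(a, axis=1, bitorder="little")
    return np.ascontiguousarray(pk).view(np.uint64)


def _unpack_bits(bits: np.ndarray, n: int) -> np.ndarray:
    by = bits.view(np.uint8)
    return np.flatnonzero(np.unpackbits(by, bitorder="little")[:n])


def _enumerate_index(
    gp: Network,
    min_side: int,
    max_results: int,
    max_explored: Optional[int],
) -> tuple[list[tuple[tuple, tuple]], bool, int]:
    """Kernel wrapper: sorted list of (side_a, side_b) node-index tuples."""
    if gp.mode != UNWEIGHTED:
        raise ConfigError("biclique enumeration operates on the unweighted view G'")
    if min_side < 1:
        raise ConfigError("min_side must be >= 1")
    if max_explored is None:
        max_explored = 20 * max_results
    n = gp.n
    if n == 0:
        return [], False, 0
    A = gp.adjacency_matrix()
    if not A.any():
        return [], False, 0
    packed = _pack_bool(A)
    res_s, res_f, truncated, explored = _biclique_kernel(
        packed, n, min_side, max_results, max_explored
    )
    if truncated:
        logger.warning(
            "biclique enumeration truncated after %d closed sets / %d results",
            explored, len(res_s),
        )
    out = []
    for k in range(len(res_s)):
        sa = tuple(_unpack_bits(res_s[k], n).tolist())
        sb = tuple(_unpack_bits(res_f[k], n).tolist())
        out.append((sa, sb))
    out.sort()
    return out, truncated, explored


def enumerate_maximal_bicliques(
    gp: Network,
    min_side: int = 3,
    max_results: int = DEFAULT_MAX_RESULTS,
    max_explored: Optional[int] = None,
) -> BicliqueEnumeration:
    """All maximal non-induced bicliques of G' with both sides >= min_side.

    Emitted in deterministic order (lexicographic by sorted side A, then
    side B, with side A the lexicographically smaller side).  The search
    stops and flags truncation once ``max_results`` bicliques have been
    emitted, or once ``max_explored`` closed sets have been visited
    (default 20x ``max_results``) — a guard against exponential blowup
    on dense graphs.
    """
    out, truncated, explored = _enumerate_index(gp, min_side, max_results, max_explored)
    nodes = gp.nodes
    bicliques = [
        Biclique(frozenset(nodes[i] for i in sa), frozenset(nodes[i] for i in sb))
        for sa, sb in out
    ]
    return BicliqueEnumeration(bicliques, truncated, explored)


# -- DICER-style cleaning --------------------------------------------


@dataclass(frozen=True)
class CleanedPair:
    side_a: frozenset
    side_b: frozenset
    p_value: float


def dicer_clean(
    h: Network,
    g: Network,
    bic: Biclique,
    min_size: int = 5,
    method: str = HYPERGEOM_FISHER,
    counter: Optional[TestCounter] = None,
) -> Optional[CleanedPair]:
    """Clean a biclique against H; reject if either side drops below min_size.

    Iteratively removes from each side the node whose summed H-weight to
    the rest of its own side is lowest, while that sum is <= 0 (a node
    must be positively tied to its own side to stay).  Each side only
    shrinks and cleaning terminates in at most |side| steps per side.
    """
    W = h.weight_matrix()
    sides = []
    for side in (bic.side_a, bic.side_b):
        idx = _clean_side(W, list(h.indices(sorted(side))))
        sides.append(idx)
    if any(len(s) < min_size for s in sides):
        return None
    a = frozenset(h.nodes[i] for i in sides[0])
    b = frozenset(h.nodes[i] for i in sides[1])
    res = link_pvalue(g, a, b, method=method, counter=counter)
    return CleanedPair(a, b, res.combined_p)


def _clean_side(W: np.ndarray, idx: list[int]) -> list[int]:
    while len(idx) > 1:
        sub = W[np.ix_(idx, idx)]
        sums = sub.sum(axis=1)
        worst = int(np.argmin(sums))
        if sums[worst] > 0:
            break
        idx.pop(worst)
    if len(idx) == 1:
        idx = []  # an isolated survivor has no positive tie to its side
    return idx


# -- MBC-DICER initiator ---------------------------------------------


def mbc_dicer_init(
    h: Network,
    g: Network,
    min_size: int = 5,
    min_side: Optional[int] = None,
    max_results: int = DEFAULT_MAX_RESULTS,
    method: str = HYPERGEOM_FISHER,
    counter: Optional[TestCounter] = None,
) -> InitialSolution:
    """Seed linked module pairs from cleaned maximal bicliques of G'.

    Because a module must be connected in H, each biclique side is first
    split into connected components of its induced positive-H subgraph
    (a maximal biclique of G' may span several modules linked to the
    same partner); every cross pair of sufficiently large components is
    then cleaned.  Cleaned pairs are ranked by their combined
    module-internal H score and accepted greedily; nodes are claimed
    first-come, a later pair keeps whatever remainder of a side is
    still unclaimed, and a side survives only if the remainder has at
    least ``min_size`` nodes.  A seed link is recorded when both sides
    of a pair survive.
    """
    gp = g if g.mode == UNWEIGHTED else g.binarize()
    if min_side is None:
        min_side = min_size  # smaller sides cannot survive cleaning anyway
    raw, _truncated, _explored = _enumerate_index(gp, min_side, max_results, None)

    W = h.weight_matrix()
    ah = W > 0

    def h_components(idx: tuple) -> list[list[int]]:
        idx = list(idx)
        sub = ah[np.ix_(idx, idx)]
        n_loc = len(idx)
        seen = np.zeros(n_loc, dtype=bool)
        comps = []
        for start in range(n_loc):
            if seen[start]:
                continue
            stack_loc = [start]
            seen[start] = True
            comp = []
            while stack_loc:
                i = stack_loc.pop()
                comp.append(i)
                for j in np.flatnonzero(sub[i] & ~seen):
                    seen[j] = True
                    stack_loc.append(int(j))
            if len(comp) >= min_size:
                comps.append(sorted(idx[i] for i in comp))
        return comps

    # clean every cross pair of sufficiently large H-components
    cleaned: dict[tuple[tuple, tuple], float] = {}
    seen_raw: set[tuple[tuple, tuple]] = set()
    for sa, sb in raw:
        for ca in h_components(sa):
            for cb in h_components(sb):
                ta, tb = tuple(ca), tuple(cb)
                if tb < ta:
                    ta, tb = tb, ta
                if (ta, tb) in seen_raw:
                    continue
                seen_raw.add((ta, tb))
                ka = tuple(_clean_side(W, list(ta)))
                kb = tuple(_clean_side(W, list(tb)))
                if len(ka) < min_size or len(kb) < min_size:
                    continue
                if kb < ka:
                    ka, kb = kb, ka
                if (ka, kb) not in cleaned:
                    # combined internal H score of the two sides
                    score = (
                        W[np.ix_(ka, ka)].sum() + W[np.ix_(kb, kb)].sum()
                    ) / 2.0
                    cleaned[(ka, kb)] = float(score)
    ranked = sorted(cleaned.items(), key=lambda kv: (-kv[1], kv[0]))

    claimed = np.zeros(h.n, dtype=bool)
    sets: list[frozenset] = []
    links: list[tuple[int, int]] = []
    link_ps: dict[tuple[int, int], float] = {}
    for (ka, kb), _score in ranked:
        rema = [i for i in ka if not claimed[i]]
        remb = [i for i in kb if not claimed[i]]
        ia = ib = None
        if len(rema) >= min_size:
            ia = len(sets)
            sets.append(frozenset(h.nodes[i] for i in rema))
            claimed[rema] = True
        if len(remb) >= min_size:
            ib = len(sets)
            sets.append(frozenset(h.nodes[i] for i in remb))
            claimed[remb] = True
        if ia is not None and ib is not None:
            links.append((ia, ib))
            res = link_pvalue(g, sets[ia], sets[ib], method=method, counter=counter)
            link_ps[(ia, ib)] = res.combined_p
    return InitialSolution(sets, links, link_ps)


# -- DICER_k initiator -----------------------------------------------


def dicer_k_init(h: Network, g: Network, k: int = 5) -> InitialSolution:
    """Seed linked pairs one at a time from heavy G' cross-structures.

    Each unclaimed G'-edge (heaviest first) seeds a pair of singleton
    sides; sides grow greedily by the node with the best positive gain
    (own-side H-weight plus cross G-weight) until no gain remains.  The
    grown pair then goes through the cleaning step (nodes without a
    positive H-tie to their own side are removed); a pair is kept when
    both cleaned sides reach size >= k and the pair qualifies as linked
    under the local rule — the summed cross G-weight is positive — and
    its nodes then leave the candidate pool.
    """
    if k < 2:
        raise ConfigError("k must be >= 2")
    WH = h.weight_matrix()
    WG = g.weight_matrix()
    gp = g if g.mode == UNWEIGHTED else g.binarize()
    n = h.n
    edge_rows = []
    for i, j in zip(*np.nonzero(np.triu(gp.adjacency_matrix(), 1))):
        edge_rows.append((-WG[i, j], gp.nodes[i], gp.nodes[j]))
    edge_rows.sort()
    pool = np.ones(n, dtype=bool)
    sets: list[frozenset] = []
    links: list[tuple[int, int]] = []
    for _, u, v in edge_rows:
        iu, iv = h.index(u), h.index(v)
        if not (pool[iu] and pool[iv]):
            continue
        in_u = np.zeros(n, dtype=bool)
        in_v = np.zeros(n, dtype=bool)
        in_u[iu] = True
        in_v[iv] = True
        gain_u = WH[:, iu] + WG[:, iv]  # gain of joining side U
        gain_v = WH[:, iv] + WG[:, iu]
        while True:
            avail = pool & ~in_u & ~in_v
            if not avail.any():
                break
            gu = np.where(avail, gain_u, -np.inf)
            gv = np.where(avail, gain_v, -np.inf)
            bu, bv = int(np.argmax(gu)), int(np.argmax(gv))
            best_gain = max(gu[bu], gv[bv])
            if best_gain <= 0:
                break
            if gu[bu] >= gv[bv]:
                w, side = bu, "u"
            else:
                w, side = bv, "v"
            # smallest-index tie break across both sides
            if gu[bu] == gv[bv] and bv < bu:
                w, side = bv, "v"
            if side == "u":
                in_u[w] = True
                gain_u += WH[:, w]
                gain_v += WG[:, w]
            else:
                in_v[w] = True
                gain_v += WH[:, w]
                gain_u += WG[:, w]
        cu = _clean_side(WH, sorted(np.flatnonzero(in_u).tolist()))
        cv = _clean_side(WH, sorted(np.flatnonzero(in_v).tolist()))
        if (
            len(cu) >= k
            and len(cv) >= k
            and WG[np.ix_(cu, cv)].sum() > 0
        ):
            a = frozenset(h.nodes[i] for i in cu)
            b = frozenset(h.nodes[i] for i in cv)
            ia, ib = len(sets), len(sets) + 1
            sets.extend([a, b])
            links.append((ia, ib))
            pool[cu] = False
            pool[cv] = False
    return InitialSolution(sets, links)


# -- hierarchical clustering initiator --------------------------------


def hclust_init(h: Network, min_size: int = 5, max_size: int = 50) -> InitialSolution:
    """Average-linkage clustering of H cut into clusters within [min, max].

    The distance between two nodes is (w_max - w(u, v)); the cluster
    tree is cut largest-first: any cluster above ``max_size`` is split
    into its children, clusters within the band are accepted and smaller
    fragments are dropped.  Returns unlinked sets.
    """
    if h.n == 0:
        raise DomainError("empty network")
    if min_size > max_size:
        raise ConfigError("min_size must be <= max_size")
    if h.n == 1:
        return InitialSolution([], [])
    W = h.weight_matrix()
    off = ~np.eye(h.n, dtype=bool)
    d = float(W[off].max()) - W
    np.fill_diagonal(d, 0.0)
    z = hierarchy.linkage(squareform(d, checks=False), method="average")
    tree = hierarchy.to_tree(z)
    sets: list[frozenset] = []

    def cut(node) -> None:
        size = node.get_count()
        if size > max_size and not node.is_leaf():
            cut(node.get_left())
            cut(node.get_right())
        elif min_size <= size <= max_size:
            leaves = node.pre_order(lambda leaf: leaf.id)
            sets.append(frozenset(h.nodes[i] for i in leaves))

    cut(tree)
    sets.sort(key=lambda s: tuple(sorted(s)))
    return InitialSolution(sets, [])


# -- greedy node-addition initiator -----------------------------------


def greedy_init(h: Network, min_size: int = 5) -> InitialSolution:
    """Grow modules in H greedily from heavy seed edges.

    The heaviest unused H-edge seeds a module; nodes with the largest
    positive marginal internal-score gain join until no positive gain
    remains.  Modules of size >= min_size are accepted and their members
    retired.  Returns unlinked sets.
    """
    if h.n == 0:
        raise DomainError("empty network")
    W = h.weight_matrix()
    n = h.n
    edge_rows = []
    for i, j in zip(*np.nonzero(np.triu(W > 0, 1))):
        edge_rows.append((-W[i, j], h.nodes[i], h.nodes[j]))
    edge_rows.sort()
    used = np.zeros(n, dtype=bool)
    sets: list[frozenset] = []
    for _, u, v in edge_rows:
        iu, iv = h.index(u), h.index(v)
        if used[iu] or used[iv]:
            continue
        in_s = np.zeros(n, dtype=bool)
        in_s[iu] = in_s[iv] = True
        gain = W[:, iu] + W[:, iv]
        while True:
            avail = ~used & ~in_s
            if not avail.any():
                break
            gm = np.where(avail, gain, -np.inf)
            w = int(np.argmax(gm))
            if gm[w] <= 0:
                break
            in_s[w] = True
            gain += W[:, w]
        if int(in_s.sum()) >= min_size:
            sets.append(frozenset(np.array(h.nodes)[in_s]))
            used |= in_s
    return InitialSolution(sets, [])
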