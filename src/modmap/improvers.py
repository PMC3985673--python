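"""Local and global improvement of an initial module collection.

The *global improver* works on a collection of disjoint node sets — the
initiator's seeds plus every unassigned node as a singleton.  Link
status (linked / anti-linked / unknown, with its p-value) is maintained
for every live pair of sets; anti-links are sticky and inherited by
merged sets, which is what keeps the quadratic candidate space
tractable.  At every iteration the improver evaluates merge proposals
(module-module and module-singleton pairs sharing at least one H- or
G'-edge), each scored by the exact change in the global score it would
realise, and greedily applies the best one — or, in batch mode, a
maximal set of pairwise-disjoint positive proposals, re-validated at
application time so the global score never decreases.

The *local improver* operates link by link, alternating single-node
additions with merges of two links that share a module.  It cannot
create modules absent from the initial solution.

``finalize_map`` turns an improver state into a ModuleMap: small sets
are dropped, links are accepted at alpha (or at 0.05 / #tests under the
Bonferroni option), and modules left without any link are removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .graph_core import (
    ConfigError,
    DomainError,
    MapLink,
    ModuleMap,
    Network,
    UNWEIGHTED,
)
from .initiators import InitialSolution
from .link_stats import (
    ANTI_LINKED,
    DEFAULT_ALPHA,
    DEFAULT_BETA,
    HYPERGEOM_FISHER,
    LINKED,
    LinkStatus,
    TestCounter,
    WILCOXON_STOUFFER,
    classify_link,
    combined_pvalue_hypergeom,
    link_pvalue,
)

logger = logging.getLogger("modmap")

GAIN_EPS = 1e-9
_INHERITED = "inherited"


@dataclass
class MergeProposal:
    """A candidate merge of two live sets with its exact score gain."""

    a: int
    b: int
    gain: float
    y_links: dict[int, tuple[float, float]]  # partner id -> (p, link weight)


class StateError(ConfigError):
    """Operation referenced a dead or unknown set id."""


class ImproverState:
    """Disjoint working sets with cached pairwise link status.

    Cross-set H-weights, G-weights and G'-edge counts are maintained
    additively under merges, so merge gains and the global score are
    cheap to evaluate exactly.
    """

    def __init__(
        self,
        h: Network,
        g: Network,
        seeds: Iterable[frozenset],
        alpha: float = DEFAULT_ALPHA,
        beta: float = DEFAULT_BETA,
        method: str = HYPERGEOM_FISHER,
        counter: Optional[TestCounter] = None,
    ):
        if not (0.0 < alpha < beta <= 1.0):
            raise ConfigError(f"need 0 < alpha < beta <= 1, got {alpha}, {beta}")
        self.h, self.g = h, g
        self.alpha, self.beta = alpha, beta
        self.method = method
        self.counter = counter if counter is not None else TestCounter()
        self._gp = g if g.mode == UNWEIGHTED else g.binarize()
        self._ab = self._gp.adjacency_matrix()
        self._deg = self._ab.sum(axis=1)
        self._wh = h.weight_matrix()
        self._wg = g.weight_matrix()
        self._ah = self._wh > 0

        seeds = [frozenset(s) for s in seeds]
        covered: set = set()
        for s in seeds:
            if covered & s:
                raise DomainError("seed sets must be pairwise disjoint")
            covered |= s
        singles = [frozenset([u]) for u in h.nodes if u not in covered]
        members = sorted(seeds, key=lambda s: tuple(sorted(s))) + singles

        n_sets = len(members)
        cap = max(2 * n_sets, n_sets + 4)
        self._cap = cap
        self.sets: dict[int, frozenset] = {i: m for i, m in enumerate(members)}
        self._alive = np.zeros(cap, dtype=bool)
        self._alive[:n_sets] = True
        self._next = n_sets
        self._idx: dict[int, np.ndarray] = {
            i: h.indices(sorted(m)) for i, m in self.sets.items()
        }
        ind = np.zeros((n_sets, h.n))
        for i, m in self.sets.items():
            ind[i, self._idx[i]] = 1.0
        self._ch = np.zeros((cap, cap))
        self._cwg = np.zeros((cap, cap))
        self._ce = np.zeros((cap, cap))
        self._ceh = np.zeros((cap, cap))
        self._ch[:n_sets, :n_sets] = ind @ self._wh @ ind.T
        self._cwg[:n_sets, :n_sets] = ind @ self._wg @ ind.T
        self._ce[:n_sets, :n_sets] = ind @ self._ab @ ind.T
        self._ceh[:n_sets, :n_sets] = ind @ self._ah @ ind.T
        for m in (self._ch, self._cwg, self._ce, self._ceh):
            np.fill_diagonal(m, 0.0)
        self.internal = np.zeros(cap)
        for i in self.sets:
            idx = self._idx[i]
            if len(idx) > 1:
                self.internal[i] = self._wh[np.ix_(idx, idx)].sum() / 2.0

        # pairwise link cache: key (i, j) i < j -> LinkStatus; "inherited"
        # anti-links carry p None
        self.link_cache: dict[tuple[int, int], LinkStatus] = {}
        self._nonanti: dict[int, set[int]] = {i: set() for i in self.sets}
        self._ytest: dict[tuple[int, int, int], float] = {}
        self._fill_initial_cache()

    # -- bookkeeping -------------------------------------------------

    def live_ids(self) -> list[int]:
        return [i for i in self.sets if self._alive[i]]

    @property
    def test_counter(self) -> int:
        return self.counter.n

    def _key(self, a: int, b: int) -> tuple[int, int]:
        return (a, b) if a < b else (b, a)

    def status(self, a: int, b: int) -> LinkStatus:
        try:
            return self.link_cache[self._key(a, b)]
        except KeyError:
            raise StateError(f"no cached status for sets {a}, {b}") from None

    def is_anti(self, a: int, b: int) -> bool:
        return self.status(a, b).status == ANTI_LINKED

    def is_linked(self, a: int, b: int) -> bool:
        return self.status(a, b).status == LINKED

    def _pair_p(self, idx_u: np.ndarray, idx_v: np.ndarray) -> float:
        self.counter.bump()
        if self.method == HYPERGEOM_FISHER:
            return combined_pvalue_hypergeom(self._ab, self._deg, idx_u, idx_v)
        nodes = np.array(self.h.nodes)
        res = link_pvalue(
            self.g, nodes[idx_u], nodes[idx_v], method=WILCOXON_STOUFFER
        )
        return res.combined_p

    def _test_pair(self, a: int, b: int) -> LinkStatus:
        """Test a live pair and cache the outcome (no-cross-edge pairs score 1)."""
        key = self._key(a, b)
        cached = self.link_cache.get(key)
        if cached is not None:
            return cached
        if self._ce[a, b] == 0 and self.method == HYPERGEOM_FISHER:
            self.counter.bump()
            p = 1.0
        else:
            p = self._pair_p(self._idx[a], self._idx[b])
        st = classify_link(p, self.alpha, self.beta)
        self.link_cache[key] = st
        if st.status != ANTI_LINKED:
            self._nonanti[a].add(b)
            self._nonanti[b].add(a)
        return st

    def _fill_initial_cache(self) -> None:
        ids = self.live_ids()
        for i_pos, a in enumerate(ids):
            for b in ids[i_pos + 1:]:
                self._test_pair(a, b)

    # -- scores ------------------------------------------------------

    def linked_partners(self, a: int) -> list[int]:
        return [z for z in self._nonanti[a] if self._alive[z] and self.is_linked(a, z)]

    def global_score(self) -> float:
        score = float(self.internal[self._alive].sum())
        for (a, b), st in self.link_cache.items():
            if st.status == LINKED and self._alive[a] and self._alive[b]:
                score += float(self._cwg[a, b])
        return score

    def accepted_links(self) -> dict[tuple[int, int], MapLink]:
        out = {}
        for (a, b), st in self.link_cache.items():
            if st.status == LINKED and self._alive[a] and self._alive[b]:
                out[(a, b)] = MapLink(st.p_value, float(self._cwg[a, b]))
        return out

    # -- merge machinery ---------------------------------------------

    def propose(self, a: int, b: int) -> MergeProposal:
        """Exact score gain of merging live sets a and b.

        Links of the merged set are determined against every live set
        that is not anti-linked to a or to b (anti-links are inherited
        without testing); the gain equals global_score(after) -
        global_score(before).
        """
        if not (self._alive[a] and self._alive[b]) or a == b:
            raise StateError(f"bad merge pair ({a}, {b})")
        y_links: dict[int, tuple[float, float]] = {}
        partners = (self._nonanti[a] | self._nonanti[b]) - {a, b}
        idx_y: Optional[np.ndarray] = None
        for z in sorted(partners):
            if not self._alive[z]:
                continue
            if self.is_anti(a, z) or self.is_anti(b, z):
                continue  # sticky anti-link, inherited silently
            key = (self._key(a, b)[0], self._key(a, b)[1], z)
            p = self._ytest.get(key)
            if p is None:
                if self._ce[a, z] + self._ce[b, z] == 0 and self.method == HYPERGEOM_FISHER:
                    p = 1.0
                    self.counter.bump()
                else:
                    if idx_y is None:
                        idx_y = np.concatenate([self._idx[a], self._idx[b]])
                    p = self._pair_p(idx_y, self._idx[z])
                self._ytest[key] = p
            if p <= self.alpha:
                y_links[z] = (p, float(self._cwg[a, z] + self._cwg[b, z]))
        new_w = sum(w for _, w in y_links.values())
        old_w = 0.0
        for z in self.linked_partners(a):
            if z != b:
                old_w += float(self._cwg[a, z])
        for z in self.linked_partners(b):
            if z != a:
                old_w += float(self._cwg[b, z])
        if self.is_linked(a, b):
            old_w += float(self._cwg[a, b])
        gain = float(self._ch[a, b]) + new_w - old_w
        return MergeProposal(a, b, gain, y_links)

    def merge(self, prop: MergeProposal) -> int:
        """Apply a merge proposal; returns the id of the new set."""
        a, b = prop.a, prop.b
        if not (self._alive[a] and self._alive[b]):
            raise StateError("merge references a dead set")
        w = self._next
        self._next += 1
        if w >= self._cap:
            self._grow()
        self.sets[w] = self.sets[a] | self.sets[b]
        self._idx[w] = np.sort(np.concatenate([self._idx[a], self._idx[b]]))
        self.internal[w] = self.internal[a] + self.internal[b] + self._ch[a, b]
        for m in (self._ch, self._cwg, self._ce, self._ceh):
            m[w, :] = m[a, :] + m[b, :]
            m[:, w] = m[:, a] + m[:, b]
            m[w, w] = 0.0
        self._alive[a] = self._alive[b] = False
        self._alive[w] = True
        self._nonanti[w] = set()
        for z in self.live_ids():
            if z == w:
                continue
            key = self._key(w, z)
            if self.is_anti(a, z) or self.is_anti(b, z):
                self.link_cache[key] = LinkStatus(ANTI_LINKED, None)
                continue
            p = prop.y_links.get(z, (None,))[0]
            if p is None:
                p = self._ytest.get((self._key(a, b)[0], self._key(a, b)[1], z))
            if p is None:
                if self._ce[w, z] == 0 and self.method == HYPERGEOM_FISHER:
                    p = 1.0
                    self.counter.bump()
                else:
                    p = self._pair_p(self._idx[w], self._idx[z])
            st = classify_link(p, self.alpha, self.beta)
            self.link_cache[key] = st
            if st.status != ANTI_LINKED:
                self._nonanti[w].add(z)
                self._nonanti[z].add(w)
        for z in (self._nonanti.pop(a, set()) | self._nonanti.pop(b, set())):
            self._nonanti.get(z, set()).discard(a)
            self._nonanti.get(z, set()).discard(b)
        return w

    def _grow(self) -> None:
        new_cap = self._cap * 2
        for name in ("_ch", "_cwg", "_ce", "_ceh"):
            old = getattr(self, name)
            m = np.zeros((new_cap, new_cap))
            m[: self._cap, : self._cap] = old
            setattr(self, name, m)
        for name, dtype in (("_alive", bool), ("internal", float)):
            old = getattr(self, name)
            v = np.zeros(new_cap, dtype=dtype)
            v[: self._cap] = old
            setattr(self, name, v)
        self._cap = new_cap

    def candidate_pairs(self) -> list[tuple[int, int]]:
        """Merge candidates: pairs sharing >= 1 H-edge or G'-edge, not both singletons."""
        ids = np.array(self.live_ids())
        sizes = np.array([len(self.sets[i]) for i in ids])
        ce = self._ce[np.ix_(ids, ids)] + self._ceh[np.ix_(ids, ids)]
        out = []
        ii, jj = np.nonzero(np.triu(ce > 0, 1))
        for i, j in zip(ii, jj):
            if sizes[i] > 1 or sizes[j] > 1:
                out.append((int(ids[i]), int(ids[j])))
        return out


def merge_gain(
    h: Network,
    g: Network,
    state: ImproverState,
    a: int,
    b: int,
) -> MergeProposal:
    """Exact global-score gain of merging sets ``a`` and ``b`` of ``state``."""
    return state.propose(a, b)


# -- global improver --------------------------------------------------


def global_improve(
    h: Network,
    g: Network,
    init: InitialSolution,
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
    min_size: int = 5,
    batch: bool = True,
    method: str = HYPERGEOM_FISHER,
    counter: Optional[TestCounter] = None,
    score_log: Optional[list] = None,
) -> ImproverState:
    """Greedy merging to a local maximum of the global score.

    Each iteration evaluates all merge proposals; in batch mode a
    maximal pairwise-disjoint family of positive-gain proposals is
    applied in descending gain order (each re-validated against the
    current state before application, so the realised global score is
    non-decreasing); otherwise only the single best merge is applied.
    Terminates when no proposal has positive gain.
    """
    state = ImproverState(h, g, init.sets, alpha=alpha, beta=beta, method=method, counter=counter)
    score = state.global_score()
    if score_log is not None:
        score_log.append(score)
    while True:
        proposals = []
        for (a, b) in state.candidate_pairs():
            pr = state.propose(a, b)
            if pr.gain > GAIN_EPS:
                proposals.append(pr)
        if not proposals:
            break
        proposals.sort(
            key=lambda pr: (
                -pr.gain,
                min(min(state.sets[pr.a]), min(state.sets[pr.b])),
                max(min(state.sets[pr.a]), min(state.sets[pr.b])),
            )
        )
        merged_any = False
        used: set[int] = set()
        for pr in proposals:
            if pr.a in used or pr.b in used:
                continue
            fresh = state.propose(pr.a, pr.b)  # cheap: re-uses cached tests
            if fresh.gain <= GAIN_EPS:
                continue
            state.merge(fresh)
            used.add(pr.a)
            used.add(pr.b)
            merged_any = True
            if not batch:
                break
        new_score = state.global_score()
        if score_log is not None:
            score_log.append(new_score)
        if new_score < score - 1e-6:
            raise AssertionError("global score decreased during improvement")
        score = new_score
        if not merged_any:
            break
    return state


# -- local improver ---------------------------------------------------


def local_improve(
    h: Network,
    g: Network,
    init: InitialSolution,
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
    method: str = HYPERGEOM_FISHER,
    counter: Optional[TestCounter] = None,
) -> ImproverState:
    """Extend seed links by single-node additions and link merges.

    For each seed link, the unassigned node with the best positive
    summed contribution (H-weight to its side plus G-weight across the
    link) is added; two links sharing a module are merged when the
    combined pair's score improves.  Repeats to a fixpoint.  Cannot
    create modules that are absent from the initial solution.
    """
    counter = counter if counter is not None else TestCounter()
    if not init.seed_links:
        logger.warning("local improver: no seed links; returning the initial solution")
        return ImproverState(h, g, init.sets, alpha=alpha, beta=beta, method=method, counter=counter)

    wh, wg = h.weight_matrix(), g.weight_matrix()
    nodes = h.nodes
    sets = {i: set(s) for i, s in enumerate(init.sets)}
    links = {tuple(sorted(l)) for l in init.seed_links}
    assigned = set().union(*sets.values())
    free = [u for u in nodes if u not in assigned]

    def contribution(u: str, own: set, other: set) -> float:
        ui = h.index(u)
        oi = h.indices(own)
        ti = h.indices(other)
        return float(wh[ui, oi].sum() + wg[ui, ti].sum())

    changed = True
    while changed:
        changed = False
        # (a) single-node additions, one per link side per pass
        for (ia, ib) in sorted(links):
            for own_id, other_id in ((ia, ib), (ib, ia)):
                best = None
                for u in free:
                    c = contribution(u, sets[own_id], sets[other_id])
                    if c > GAIN_EPS and (best is None or c > best[0] or (c == best[0] and u < best[1])):
                        best = (c, u)
                if best is not None:
                    sets[own_id].add(best[1])
                    free.remove(best[1])
                    changed = True
        # (b) merge two links sharing a module when the pair score improves
        done_merge = False
        for (ia, ib) in sorted(links):
            if done_merge:
                break
            for (ic, idd) in sorted(links):
                if (ic, idd) == (ia, ib):
                    continue
                shared = {ia, ib} & {ic, idd}
                if len(shared) != 1:
                    continue
                s = shared.pop()
                v = ({ia, ib} - {s}).pop()
                w = ({ic, idd} - {s}).pop()
                vi = h.indices(sets[v])
                wi = h.indices(sets[w])
                if wh[np.ix_(vi, wi)].sum() > GAIN_EPS:
                    sets[v] |= sets[w]
                    del sets[w]
                    links = {
                        tuple(sorted((v if x == w else x, v if y == w else y)))
                        for (x, y) in links
                        if {x, y} != {v, w}
                    }
                    links = {l for l in links if l[0] != l[1]}
                    changed = done_merge = True
                    break

    final_sets = [frozenset(sets[i]) for i in sorted(sets)]
    # the returned state re-tests all pairs of the final collection, so the
    # grown links carry p-values reflecting their final membership
    return ImproverState(
        h, g, final_sets, alpha=alpha, beta=beta, method=method, counter=counter
    )


# -- finalization ------------------------------------------------------


def finalize_map(
    state: ImproverState,
    h: Network,
    g: Network,
    min_size: int = 5,
    alpha: float = DEFAULT_ALPHA,
    correction: str = "none",
) -> ModuleMap:
    """Extract the module map from an improver state.

    Sets below ``min_size`` are dropped; links are accepted at p <=
    alpha (``correction="none"``) or p <= 0.05 / #tests
    (``correction="bonferroni"``); modules left without a single link
    are dropped, cascading until stable.
    """
    if correction not in ("none", "bonferroni"):
        raise ConfigError(f"unknown correction {correction!r}")
    thr = alpha if correction == "none" else 0.05 / max(state.test_counter, 1)
    survivors = {
        i: state.sets[i]
        for i in state.live_ids()
        if len(state.sets[i]) >= min_size
    }
    links = {
        (a, b): st.p_value
        for (a, b), st in state.link_cache.items()
        if st.status == LINKED
        and a in survivors
        and b in survivors
        and st.p_value is not None
        and st.p_value <= thr
    }
    while True:
        linked_ids = set()
        for (a, b) in links:
            linked_ids.add(a)
            linked_ids.add(b)
        dropped = set(survivors) - linked_ids
        if not dropped:
            break
        for i in dropped:
            del survivors[i]
        links = {k: v for k, v in links.items() if k[0] in survivors and k[1] in survivors}
        if not survivors:
            logger.warning("finalized map is empty")
            break
    order = sorted(survivors, key=lambda i: tuple(sorted(survivors[i])))
    remap = {i: k for k, i in enumerate(order)}
    modules = [frozenset(survivors[i]) for i in order]
    out_links = {}
    for (a, b), p in links.items():
        i, j = sorted((remap[a], remap[b]))
        out_links[(i, j)] = MapLink(p, float(state._cwg[a, b]))
    return ModuleMap(modules, out_links)
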