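"""Statistical tests for module-to-module links.

Whether two node sets U and V are "linked" in G is decided by a combined
per-node test.  On the thresholded unweighted view G' each node is scored
by an upper-tail hypergeometric test for an enriched number of edges into
the opposite set, and the per-node p-values are merged with Fisher's
method.  On weighted G each node is scored by a one-sided Wilcoxon
rank-sum test comparing its edge weights into the opposite set against
its edge weights to the rest of the network, merged with Stouffer's
method.  A pair is a *link* when the combined p-value is at most alpha
and an *anti-link* when it is at least beta (alpha < beta); anti-links
are cached and never re-tested by the improvers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .graph_core import DomainError, ConfigError, Network, UNWEIGHTED

DEFAULT_ALPHA = 0.005
DEFAULT_BETA = 0.2
P_FLOOR = 1e-300

HYPERGEOM_FISHER = "hypergeom_fisher"
WILCOXON_STOUFFER = "wilcoxon_stouffer"

LINKED = "linked"
ANTI_LINKED = "anti_linked"
UNKNOWN = "unknown"

# exact rank-sum enumeration below this per-side size (ties force the
# mid-rank normal approximation either way)
_WILCOXON_EXACT_MAX = 20


class TestCounter:
    """Counts link-test evaluations (used for the Bonferroni option)."""

    __slots__ = ("n",)

    def __init__(self) -> None:
        self.n = 0

    def bump(self, k: int = 1) -> None:
        self.n += k


@dataclass
class LinkTestResult:
    per_node_pvalues: dict[str, float]
    combined_p: float
    method: str
    n_tests_recorded: int = 1


@dataclass(frozen=True)
class LinkStatus:
    """Outcome of a link test: linked / anti_linked / unknown plus its p."""

    status: str
    p_value: Optional[float]


def classify_link(p: float, alpha: float = DEFAULT_ALPHA, beta: float = DEFAULT_BETA) -> LinkStatus:
    """Classify a combined link p-value against the (alpha, beta) thresholds."""
    if not (0.0 < alpha < beta <= 1.0):
        raise ConfigError(f"need 0 < alpha < beta <= 1, got alpha={alpha}, beta={beta}")
    if p <= alpha:
        return LinkStatus(LINKED, p)
    if p >= beta:
        return LinkStatus(ANTI_LINKED, p)
    return LinkStatus(UNKNOWN, p)


# -- p-value combination ---------------------------------------------


def combine_fisher(pvals: Sequence[float]) -> float:
    """Fisher's method: chi-square upper tail of -2 * sum(log p) with 2k df."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise DomainError("no p-values to combine")
    if np.any(pvals <= 0.0) or np.any(pvals > 1.0):
        raise DomainError("Fisher combination requires p-values in (0, 1]")
    stat = -2.0 * np.log(pvals).sum()
    return float(stats.chi2.sf(stat, 2 * pvals.size))


def combine_stouffer(pvals: Sequence[float]) -> float:
    """Stouffer's method: p of z = sum(z_i) / sqrt(k), z_i the upper quantile."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise DomainError("no p-values to combine")
    if np.any(pvals <= 0.0) or np.any(pvals >= 1.0):
        raise DomainError("Stouffer combination requires p-values in (0, 1)")
    z = stats.norm.isf(pvals)
    return float(stats.norm.sf(z.sum() / np.sqrt(pvals.size)))


# -- per-node tests --------------------------------------------------


def node_link_pvalue_hypergeom(
    gp: Network, x: str, own: Iterable[str], target: Iterable[str]
) -> float:
    """Upper-tail hypergeometric p for the edges of ``x`` into ``target``.

    The population is every node except ``x`` itself (N - 1 nodes), the
    number of successes is the G'-degree of ``x``, and the sample is
    ``target``.  Returns 1 when ``x`` has no edge into ``target``.
    """
    own, target = set(own), set(target)
    if x not in own:
        raise DomainError(f"{x!r} must belong to its own set")
    if own & target:
        raise DomainError("own and target sets overlap")
    if gp.mode != UNWEIGHTED:
        raise ConfigError("hypergeometric test requires the unweighted view G'")
    nbrs = gp.neighbors(x)
    k = len(nbrs & target)
    big_k = len(nbrs)
    big_n = gp.n - 1
    n_draw = len(target)
    return float(stats.hypergeom.sf(k - 1, big_n, big_k, n_draw))


def node_link_pvalue_wilcoxon(g: Network, x: str, target: Iterable[str]) -> float:
    """One-sided rank-sum p that weights from ``x`` into ``target`` are heavy.

    Compares {w(x, v): v in target} against {w(x, u): u not in target,
    u != x}.  Complete ties carry no evidence and return 1.  Exact
    enumeration is used for small tie-free samples, mid-rank normal
    approximation otherwise.
    """
    target = set(target)
    if not target:
        raise DomainError("target set is empty")
    if x in target:
        raise DomainError(f"{x!r} cannot be inside the target set")
    background = set(g.nodes) - target - {x}
    if not background:
        raise DomainError("empty background: target covers the whole network")
    W = g.weight_matrix()
    xi = g.index(x)
    tv = W[xi, g.indices(target)]
    bv = W[xi, g.indices(background)]
    return _ranksum_greater(tv, bv)


def _ranksum_greater(tv: np.ndarray, bv: np.ndarray) -> float:
    if tv.max(initial=-np.inf) == tv.min(initial=np.inf) and bv.size and tv.size:
        if tv.max() == bv.max() and bv.max() == bv.min():
            return 1.0
    has_ties = np.unique(np.concatenate([tv, bv])).size < tv.size + bv.size
    if not has_ties and max(tv.size, bv.size) < _WILCOXON_EXACT_MAX:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(tv, bv, alternative="greater", method=method)
    return float(min(res.pvalue, 1.0))


# -- combined link test ----------------------------------------------


def _hypergeom_side_pvalues(
    a_bool: np.ndarray, deg: np.ndarray, idx_from: np.ndarray, idx_to: np.ndarray
) -> np.ndarray:
    """Vectorised per-node hypergeometric p-values, one per node of idx_from."""
    n = a_bool.shape[0]
    k = a_bool[np.ix_(idx_from, idx_to)].sum(axis=1)
    return stats.hypergeom.sf(k - 1, n - 1, deg[idx_from], len(idx_to))


def combined_pvalue_hypergeom(
    a_bool: np.ndarray, deg: np.ndarray, idx_u: np.ndarray, idx_v: np.ndarray
) -> float:
    """Fast path: Fisher-combined two-sided-set hypergeometric link p.

    Operates directly on a boolean adjacency matrix and degree vector;
    equals :func:`link_pvalue` with the hypergeometric method.
    """
    pu = _hypergeom_side_pvalues(a_bool, deg, idx_u, idx_v)
    pv = _hypergeom_side_pvalues(a_bool, deg, idx_v, idx_u)
    ps = np.clip(np.concatenate([pu, pv]), P_FLOOR, 1.0)
    stat = -2.0 * np.log(ps).sum()
    return float(stats.chi2.sf(stat, 2 * ps.size))


def link_pvalue(
    g: Network,
    left: Iterable[str],
    right: Iterable[str],
    method: str = HYPERGEOM_FISHER,
    counter: Optional[TestCounter] = None,
) -> LinkTestResult:
    """Combined link p-value between two disjoint node sets.

    Every node of each set is tested against the opposite set; per-node
    p-values are merged by Fisher (hypergeometric method on G') or
    Stouffer (Wilcoxon method on weighted G).
    """
    left, right = sorted(set(left)), sorted(set(right))
    if not left or not right:
        raise DomainError("link sides must be non-empty")
    if set(left) & set(right):
        raise DomainError("link sides must be disjoint")
    per_node: dict[str, float] = {}
    if method == HYPERGEOM_FISHER:
        gp = g if g.mode == UNWEIGHTED else g.binarize()
        a_bool = gp.adjacency_matrix()
        deg = a_bool.sum(axis=1)
        iu, iv = gp.indices(left), gp.indices(right)
        pu = _hypergeom_side_pvalues(a_bool, deg, iu, iv)
        pv = _hypergeom_side_pvalues(a_bool, deg, iv, iu)
        for u, p in zip(left, pu):
            per_node[u] = float(p)
        for v, p in zip(right, pv):
            per_node[v] = float(p)
        ps = np.clip(np.concatenate([pu, pv]), P_FLOOR, 1.0)
        combined = combine_fisher(ps)
    elif method == WILCOXON_STOUFFER:
        for u in left:
            per_node[u] = node_link_pvalue_wilcoxon(g, u, right)
        for v in right:
            per_node[v] = node_link_pvalue_wilcoxon(g, v, left)
        ps = np.clip(list(per_node.values()), P_FLOOR, 1.0 - 1e-16)
        combined = combine_stouffer(ps)
    else:
        raise ConfigError(f"unknown link test method {method!r}")
    if counter is not None:
        counter.bump()
    return LinkTestResult(per_node, float(min(combined, 1.0)), method)
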