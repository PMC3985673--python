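"""Evaluation of recovered module maps.

Recovery against a planted truth is scored with the co-membership
pair Jaccard coefficient: the sets of unordered node pairs co-assigned
to a module are compared between the found and the true module
collections.  Two map-quality procedures for real data are also
provided: a held-out test comparing the G-weights of links against
non-links, and a per-link fold-change against the best of random
same-size module pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .graph_core import DomainError, ModuleMap, Network
from .link_stats import _ranksum_greater

_FC_FLOOR = 1e-6


@dataclass
class RecoveryReport:
    pair_jaccard: float
    n_modules_found: int
    n_genes_covered: int
    max_module_size: int
    n_links: int

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            for k, v in vars(self).items():
                fh.write(f"{k}\t{v}\n")


def _pair_set(sets: Sequence[Iterable[str]]) -> set[frozenset]:
    seen: set = set()
    pairs: set[frozenset] = set()
    for s in sets:
        s = set(s)
        if seen & s:
            raise DomainError("sets within one collection must be disjoint")
        seen |= s
        for u, v in combinations(sorted(s), 2):
            pairs.add(frozenset((u, v)))
    return pairs


def pair_jaccard(found: Sequence[Iterable[str]], truth: Sequence[Iterable[str]]) -> float:
    """Jaccard coefficient between co-membership pair sets.

    1.0 when both collections induce the same co-assigned pairs
    (including the degenerate case of two empty pair sets), 0.0 for
    disjoint supports.  Invariant under module relabelling/reordering.
    """
    pf, pt = _pair_set(found), _pair_set(truth)
    union = pf | pt
    if not union:
        return 1.0
    return len(pf & pt) / len(union)


def recovery_report(mmap: ModuleMap, truth_modules: Sequence[Iterable[str]]) -> RecoveryReport:
    return RecoveryReport(
        pair_jaccard=pair_jaccard(mmap.modules, truth_modules),
        n_modules_found=mmap.n_modules,
        n_genes_covered=mmap.genes_covered,
        max_module_size=mmap.max_module_size,
        n_links=len(mmap.links),
    )


def link_vs_nonlink_test(mmap: ModuleMap, g_test: Network) -> float:
    """Held-out link quality: one-sided rank-sum p that linked module
    pairs carry heavier mean cross weights in ``g_test`` than unlinked
    pairs."""
    if mmap.n_modules < 2:
        raise DomainError("need at least two modules")
    W = g_test.weight_matrix()
    linked_vals, nonlink_vals = [], []
    for i, j in combinations(range(mmap.n_modules), 2):
        ii = g_test.indices(mmap.modules[i])
        jj = g_test.indices(mmap.modules[j])
        mean_w = float(W[np.ix_(ii, jj)].mean())
        if (i, j) in mmap.links:
            linked_vals.append(mean_w)
        else:
            nonlink_vals.append(mean_w)
    if not linked_vals or not nonlink_vals:
        raise DomainError("need at least one link and one non-link pair")
    return _ranksum_greater(np.array(linked_vals), np.array(nonlink_vals))


def _positive_mass(W: np.ndarray, ii: np.ndarray, jj: np.ndarray) -> float:
    block = W[np.ix_(ii, jj)]
    return max(float(np.clip(block, 0.0, None).mean()), _FC_FLOOR)


def link_fold_change(
    mmap: ModuleMap,
    g: Network,
    repeats: int = 200,
    rng: Optional[np.random.Generator] = None,
) -> dict[tuple[int, int], float]:
    """Per-link fold-change against the best random same-size set pair.

    The link statistic is the mean positive cross weight (negative
    weights contribute zero, floored at a small epsilon); each link is
    divided by the maximum of the same statistic over ``repeats``
    random disjoint node-set pairs of matching sizes.
    """
    if repeats < 1:
        raise DomainError("repeats must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(0)
    W = g.weight_matrix()
    nodes = np.array(g.nodes)
    out: dict[tuple[int, int], float] = {}
    for (i, j) in sorted(mmap.links):
        ii = g.indices(mmap.modules[i])
        jj = g.indices(mmap.modules[j])
        if len(ii) + len(jj) > len(nodes):
            raise DomainError("network too small to draw disjoint random sets")
        real = _positive_mass(W, ii, jj)
        best = _FC_FLOOR
        for _ in range(repeats):
            draw = rng.choice(len(nodes), size=len(ii) + len(jj), replace=False)
            best = max(best, _positive_mass(W, draw[: len(ii)], draw[len(ii):]))
        out[(i, j)] = real / best
    return out
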