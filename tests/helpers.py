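"""Independent reference implementations (oracles) used by the tests.

Deliberately simple and separate from the package's code paths:
set-based recursive Fitch, full topology enumeration, exhaustive
changepoint searches, and breakpoint-subset enumeration for the joint
segmentation objective.
"""

from __future__ import annotations

import itertools

import numpy as np


# -- parsimony ---------------------------------------------------------------


def fitch_on_rooted(tree, states: dict) -> int:
    """Set-based Fitch on a nested-tuple rooted tree.

    ``tree`` is a taxon name or a tuple of subtrees; ``states`` maps
    taxon -> tuple of character states.
    """
    n_chars = len(next(iter(states.values())))
    total = 0

    def rec(node, c):
        nonlocal total
        if not isinstance(node, tuple):
            return {states[node][c]}
        acc = None
        for child in node:
            s = rec(child, c)
            if acc is None:
                acc = s
            else:
                inter = acc & s
                if inter:
                    acc = inter
                else:
                    acc = acc | s
                    total += 1
        return acc

    for c in range(n_chars):
        rec(tree, c)
    return total


def all_rooted_shapes(taxa):
    """All distinct rooted binary nested-tuple trees over ``taxa``."""
    taxa = list(taxa)
    if len(taxa) == 1:
        yield taxa[0]
        return
    first, rest = taxa[0], taxa[1:]
    # split rest into the clade containing `first` implicitly: enumerate by
    # joining: every rooted binary tree arises from inserting taxa one at a time
    for shape in _grow([first], rest):
        yield shape


def _grow(built, remaining):
    if not remaining:
        yield built[0]
        return
    nxt, rest = remaining[0], remaining[1:]
    for i, t in enumerate(built):
        for new_t in _insert_everywhere(t, nxt):
            yield from _grow([new_t], rest)


def _insert_everywhere(tree, leaf):
    yield (tree, leaf)
    if isinstance(tree, tuple):
        a, b = tree
        for na in _insert_everywhere(a, leaf):
            yield (na, b)
        for nb in _insert_everywhere(b, leaf):
            yield (a, nb)


def min_parsimony_exhaustive(rows: np.ndarray) -> int:
    """Global minimum Fitch score over all unrooted topologies.

    Enumerates rooted trees (every unrooted topology appears among
    them; rooting does not change the Fitch score).
    """
    names = [f"t{i}" for i in range(len(rows))]
    states = {n: tuple(r) for n, r in zip(names, rows)}
    best = np.inf
    for tree in all_rooted_shapes(names):
        s = fitch_on_rooted(tree, states)
        if s < best:
            best = s
    return int(best)


# -- changepoints ------------------------------------------------------------


def best_single_changepoint(x: np.ndarray) -> int:
    """Exhaustive max-statistic search for one changepoint (prefix split)."""
    n = len(x)
    best, best_k = -np.inf, 1
    for k in range(1, n):
        m1, m2 = x[:k].mean(), x[k:].mean()
        stat = abs(m1 - m2) / np.sqrt(1 / k + 1 / (n - k))
        if stat > best:
            best, best_k = stat, k
    return best_k


def best_k_changepoints_sse(x: np.ndarray, k: int):
    """Exhaustive min-SSE placement of exactly k interior changepoints."""
    n = len(x)
    best, best_cuts = np.inf, ()
    for cuts in itertools.combinations(range(1, n), k):
        edges = [0, *cuts, n]
        sse = sum(
            ((x[a:b] - x[a:b].mean()) ** 2).sum()
            for a, b in zip(edges[:-1], edges[1:])
        )
        if sse < best:
            best, best_cuts = sse, cuts
    return list(best_cuts), best


# -- joint segmentation objective -------------------------------------------


def joint_objective(R: np.ndarray, cuts, gamma: float) -> float:
    """SSE of shared-breakpoint per-cell fits plus gamma per breakpoint."""
    n = R.shape[0]
    edges = [0, *sorted(cuts), n]
    sse = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        block = R[a:b]
        sse += ((block - block.mean(axis=0)) ** 2).sum()
    return sse + gamma * len(cuts)


def joint_optimum_bruteforce(
    R: np.ndarray, gamma: float, max_breakpoints: int | None = None
) -> float:
    """Minimum joint objective by breakpoint-subset enumeration."""
    n = R.shape[0]
    positions = range(1, n)
    best = np.inf
    max_k = n - 1 if max_breakpoints is None else max_breakpoints
    for k in range(0, max_k + 1):
        for cuts in itertools.combinations(positions, k):
            obj = joint_objective(R, cuts, gamma)
            if obj < best:
                best = obj
    return best
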