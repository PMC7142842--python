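"""Maximum-parsimony clonal phylogeny from the trinary event matrix.

Characters are the shared autosomal segments, with unordered states
{-1, 0, +1} and unit change cost (Fitch parsimony).  Tree search uses
the parsimony ratchet: starting from a neighbor-joining tree on Hamming
distances, iterations alternate branch swapping (nearest-neighbor
interchange, then subtree-prune-regraft) on character-upweighted data
with swapping on the original weights, keeping any tree at least as
good as the incumbent.  Cells with identical event rows are collapsed
to a single search leaf and re-expanded afterwards as a polytomy, so
zero-event cells (blood, early tumor) never destabilize the search and
end up attached at the root.

Rooting is by the normal diploid blood cells (outgroup).  Ancestral
states follow the ACCTRAN rule — among minimum-change reconstructions,
changes are placed as close to the root as possible — giving integer
branch lengths (character changes per branch) that sum to the tree's
parsimony score.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .popseg import EventMatrix

__all__ = [
    "UnrootedTree",
    "CnaTree",
    "parsimony_score",
    "parsimony_ratchet",
    "exhaustive_parsimony",
    "root_and_acctran",
    "assess_clonal_origin",
]

# state encoding for Fitch set operations: state s -> bit (s + 1)
_BITS = {-1: 1, 0: 2, 1: 4}
_STATE_OF_BIT = {1: -1, 2: 0, 4: 1}
# deterministic preference when ACCTRAN leaves a tie: neutral, loss, gain
_TIE_ORDER = (2, 1, 4)


def _encode(rows: np.ndarray) -> np.ndarray:
    """Map a (leaves x chars) trinary matrix to Fitch bitmasks."""
    out = np.zeros(rows.shape, dtype=np.uint8)
    for s, b in _BITS.items():
        out[rows == s] = b
    return out


# ---------------------------------------------------------------------------
# unrooted trees as adjacency maps


class UnrootedTree:
    """Unrooted leaf-labelled tree: adjacency over integer node ids.

    Leaves are the ids present in ``labels``; internal nodes are
    unconstrained in degree (search trees are binary, expanded trees may
    contain polytomies of identical-state cells).
    """

    def __init__(self, adj: dict, labels: dict):
        self.adj = {u: set(vs) for u, vs in adj.items()}
        self.labels = dict(labels)

    @property
    def leaves(self) -> list[int]:
        return sorted(self.labels)

    @property
    def taxa(self) -> list[str]:
        return [self.labels[u] for u in self.leaves]

    def copy(self) -> "UnrootedTree":
        return UnrootedTree(self.adj, self.labels)

    def edges(self) -> list[tuple]:
        return [(u, v) for u in self.adj for v in self.adj[u] if u < v]

    def splits(self) -> frozenset:
        """Canonical nontrivial splits (side not containing the first leaf)."""
        first = min(self.labels)
        out = set()
        for u, v in self.edges():
            side = self._side(v, u)
            names = frozenset(self.labels[x] for x in side if x in self.labels)
            if first in side:
                other = frozenset(self.taxa) - names
                names = other
            if 1 < len(names) < len(self.labels) - 1:
                out.add(names)
        return frozenset(out)

    def _side(self, start: int, blocked: int) -> set:
        """Nodes reachable from ``start`` without crossing ``blocked``."""
        seen = {start}
        stack = [start]
        while stack:
            u = stack.pop()
            for w in self.adj[u]:
                if w != blocked and w not in seen:
                    seen.add(w)
                    stack.append(w)
        return seen

    def to_newick(self) -> str:
        inner = [u for u in self.adj if u not in self.labels]
        root = inner[0] if inner else min(self.adj)

        def render(u, parent):
            kids = sorted(self.adj[u] - {parent})
            if not kids:
                return self.labels[u]
            parts = [render(k, u) for k in kids]
            name = self.labels.get(u, "")
            return "(" + ",".join(parts) + ")" + name

        return render(root, None) + ";"


def _fitch_score(tree: UnrootedTree, masks: dict, weights: np.ndarray) -> float:
    """Weighted Fitch parsimony score of an unrooted tree.

    ``masks`` maps every leaf node id to its uint8 state-bitmask vector.
    Polytomies are combined pairwise in child order; exact for binary
    trees and for polytomies of identical leaves.
    """
    adj = tree.adj
    inner = [u for u in adj if u not in tree.labels]
    root = inner[0] if inner else next(iter(adj))
    order = []
    parent = {root: None}
    stack = [root]
    while stack:
        u = stack.pop()
        order.append(u)
        for w in adj[u]:
            if w != parent[u]:
                parent[w] = u
                stack.append(w)
    n_chars = len(weights)
    sets: dict[int, np.ndarray] = {}
    total = 0.0
    for u in reversed(order):
        kids = [w for w in adj[u] if parent.get(w) == u]
        if not kids:
            sets[u] = masks[u]
            continue
        cur = masks[u] if u in masks else None
        for w in kids:
            s = sets.pop(w)
            if cur is None:
                cur = s
                continue
            inter = cur & s
            miss = inter == 0
            total += weights[miss].sum()
            cur = np.where(miss, cur | s, inter)
        sets[u] = cur
    return float(total)


# ---------------------------------------------------------------------------
# search moves


def _nni_neighbors(tree: UnrootedTree):
    """Yield the two NNI rearrangements of every internal edge."""
    for u, v in tree.edges():
        if u in tree.labels or v in tree.labels:
            continue
        a_opts = sorted(tree.adj[u] - {v})
        c_opts = sorted(tree.adj[v] - {u})
        if len(a_opts) < 2 or len(c_opts) < 1:
            continue
        b = a_opts[1]
        for c in c_opts:
            t = tree.copy()
            t.adj[u].discard(b)
            t.adj[b].discard(u)
            t.adj[v].discard(c)
            t.adj[c].discard(v)
            t.adj[u].add(c)
            t.adj[c].add(u)
            t.adj[v].add(b)
            t.adj[b].add(v)
            yield t


def _spr_neighbors(tree: UnrootedTree):
    """Yield subtree-prune-regraft rearrangements."""
    new_id = max(tree.adj) + 1
    for a, b in [(x, y) for x, y in tree.edges()] + [
        (y, x) for x, y in tree.edges()
    ]:
        # prune the b-side subtree off a
        side = tree._side(b, a)
        rest = set(tree.adj) - side
        if len(rest) < 3:
            continue
        base = tree.copy()
        base.adj[a].discard(b)
        base.adj[b].discard(a)
        suppressed = None
        if a not in base.labels and len(base.adj[a]) == 2:
            x, y = sorted(base.adj[a])
            base.adj[x].discard(a)
            base.adj[y].discard(a)
            base.adj[x].add(y)
            base.adj[y].add(x)
            del base.adj[a]
            suppressed = (x, y)
            rest = rest - {a}
        rest_edges = [
            (x, y)
            for x in rest
            for y in base.adj[x]
            if x < y and y in rest
        ]
        for x, y in rest_edges:
            t = UnrootedTree(base.adj, base.labels)
            m = new_id
            t.adj[x].discard(y)
            t.adj[y].discard(x)
            t.adj[m] = {x, y, b}
            t.adj[x].add(m)
            t.adj[y].add(m)
            t.adj[b].add(m)
            yield t


def _hill_climb(
    tree: UnrootedTree, masks: dict, weights: np.ndarray
) -> tuple[UnrootedTree, float]:
    """First-improvement NNI then SPR local search."""
    best = tree
    best_score = _fitch_score(tree, masks, weights)
    improved = True
    while improved:
        improved = False
        for t in _nni_neighbors(best):
            s = _fitch_score(t, masks, weights)
            if s < best_score:
                best, best_score, improved = t, s, True
                break
        if improved:
            continue
        for t in _spr_neighbors(best):
            s = _fitch_score(t, masks, weights)
            if s < best_score:
                best, best_score, improved = t, s, True
                break
    return best, best_score


# ---------------------------------------------------------------------------
# start tree: plain neighbor joining on Hamming distances


def _nj_tree(D: np.ndarray) -> UnrootedTree:
    n = D.shape[0]
    if n == 1:
        return UnrootedTree({0: set()}, {0: 0})
    if n == 2:
        return UnrootedTree({0: {1}, 1: {0}}, {0: 0, 1: 1})
    active = list(range(n))
    adj: dict[int, set] = {i: set() for i in range(n)}
    D = D.astype(float).copy()
    idx = {i: i for i in range(n)}  # active label -> row in D
    Dm = D
    next_id = n
    labels = list(range(n))
    while len(labels) > 3:
        m = len(labels)
        r = Dm.sum(axis=1)
        Q = (m - 2) * Dm - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)
        if i > j:
            i, j = j, i
        u = next_id
        next_id += 1
        adj[u] = {labels[i], labels[j]}
        adj[labels[i]].add(u)
        adj[labels[j]].add(u)
        d_new = 0.5 * (Dm[i, :] + Dm[j, :] - Dm[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        Dm2 = np.empty((m - 1, m - 1))
        Dm2[:-1, :-1] = Dm[np.ix_(keep, keep)]
        Dm2[-1, :-1] = d_new[keep]
        Dm2[:-1, -1] = d_new[keep]
        Dm2[-1, -1] = 0.0
        labels = [labels[k] for k in keep] + [u]
        Dm = Dm2
    hub = next_id
    adj[hub] = set(labels)
    for l in labels:
        adj[l].add(hub)
    return UnrootedTree(adj, {i: i for i in range(n)})


# ---------------------------------------------------------------------------
# public scoring / search


def _matrix_rows(matrix) -> tuple[np.ndarray, list[str]]:
    if isinstance(matrix, EventMatrix):
        return matrix.states.astype(np.int8), matrix.cell_ids
    raise TypeError("matrix must be an EventMatrix")


def parsimony_score(tree: UnrootedTree, matrix) -> int:
    """Fitch parsimony score of ``tree`` on the trinary matrix."""
    rows, ids = _matrix_rows(matrix)
    row_of = {c: i for i, c in enumerate(ids)}
    missing = [t for t in tree.taxa if t not in row_of]
    if missing:
        raise ValueError(f"leaves without a matrix row: {missing}")
    enc = _encode(rows)
    masks = {u: enc[row_of[tree.labels[u]]] for u in tree.leaves}
    w = np.ones(rows.shape[1])
    return int(round(_fitch_score(tree, masks, w)))


def _expand_patterns(tree: UnrootedTree, groups: list[list[str]]) -> UnrootedTree:
    """Replace each pattern leaf by its member cells (polytomy if > 1)."""
    t = tree.copy()
    next_id = max(t.adj) + 1
    labels: dict[int, str] = {}
    for u in list(t.labels):
        members = groups[t.labels[u]]
        if len(members) == 1:
            labels[u] = members[0]
        else:
            for m in members:
                t.adj[next_id] = {u}
                t.adj[u].add(next_id)
                labels[next_id] = m
                next_id += 1
    t.labels = labels
    return t


def _star_tree(cell_ids: list[str]) -> UnrootedTree:
    n = len(cell_ids)
    hub = n
    adj = {i: {hub} for i in range(n)}
    adj[hub] = set(range(n))
    return UnrootedTree(adj, {i: cell_ids[i] for i in range(n)})


def parsimony_ratchet(
    matrix,
    n_iterations: int = 200,
    reweight_fraction: float = 0.25,
    seed: int = 0,
) -> tuple[list[UnrootedTree], int]:
    """Parsimony-ratchet search; returns all distinct best trees + score.

    Identical event rows are collapsed to one search leaf each; returned
    trees are re-expanded over all cells.  With fewer than three
    distinct rows, or no variable character, a star tree is returned
    with a warning.
    """
    if not 0 < reweight_fraction < 1:
        raise ValueError("reweight_fraction must be in (0, 1)")
    if n_iterations < 0:
        raise ValueError("n_iterations must be >= 0")
    rows, ids = _matrix_rows(matrix)
    if len(ids) < 3:
        raise ValueError("need at least 3 cells")
    uniq, inverse = np.unique(rows, axis=0, return_inverse=True)
    groups: list[list[str]] = [[] for _ in range(len(uniq))]
    for ci, g in enumerate(inverse):
        groups[g].append(ids[ci])
    n_pat = len(uniq)
    if n_pat == 1:
        warnings.warn(
            "no variable character; returning a star tree", stacklevel=2
        )
        star = _star_tree(ids)
        return [star], parsimony_score(star, matrix)
    if n_pat == 2:
        # a single topology exists: the two pattern groups joined by one edge
        two = UnrootedTree({0: {1}, 1: {0}}, {0: 0, 1: 1})
        t = _expand_patterns(two, groups)
        return [t], parsimony_score(t, matrix)

    enc = _encode(uniq)
    masks = {i: enc[i] for i in range(n_pat)}
    n_chars = uniq.shape[1]
    w1 = np.ones(n_chars)
    D = (uniq[:, None, :] != uniq[None, :, :]).sum(axis=2).astype(float)
    tree = _nj_tree(D)
    tree, best_score = _hill_climb(tree, masks, w1)
    best_trees = {tree.splits(): tree}
    rng = np.random.default_rng(seed)
    current = tree
    for _ in range(n_iterations):
        w2 = w1.copy()
        k = max(1, int(round(reweight_fraction * n_chars)))
        sel = rng.choice(n_chars, size=k, replace=False)
        w2[sel] *= 2.0
        t, _ = _hill_climb(current, masks, w2)
        t, s = _hill_climb(t, masks, w1)
        if s < best_score:
            best_score = s
            best_trees = {t.splits(): t}
            current = t
        elif s == best_score:
            best_trees.setdefault(t.splits(), t)
            current = t
    expanded = [
        _expand_patterns(t, groups) for t in best_trees.values()
    ]
    return expanded, int(round(best_score))


def _enumerate_unrooted(n: int):
    """All unrooted binary topologies over leaves 0..n-1 (3 <= n <= 9)."""
    base = UnrootedTree(
        {0: {3}, 1: {3}, 2: {3}, 3: {0, 1, 2}}, {i: i for i in range(3)}
    )

    def grow(tree: UnrootedTree, k: int):
        if k == n:
            yield tree
            return
        nid = max(tree.adj) + 1
        for u, v in tree.edges():
            t = tree.copy()
            t.adj[u].discard(v)
            t.adj[v].discard(u)
            t.adj[nid] = {u, v, nid + 1}
            t.adj[u].add(nid)
            t.adj[v].add(nid)
            t.adj[nid + 1] = {nid}
            t.labels[nid + 1] = k
            yield from grow(t, k + 1)

    if n == 3:
        yield base
    else:
        yield from grow(base, 3)


def exhaustive_parsimony(matrix) -> int:
    """Global minimum parsimony score by full topology enumeration.

    Brute force over all unrooted binary topologies on the distinct
    event patterns; practical to ~9 patterns (2,027,025 topologies at 9,
    945 at 7).  Serves as the reference for validating heuristic search
    on small instances.
    """
    rows, ids = _matrix_rows(matrix)
    uniq = np.unique(rows, axis=0)
    n = len(uniq)
    if n > 9:
        raise ValueError("exhaustive search is limited to <= 9 distinct patterns")
    enc = _encode(uniq)
    w = np.ones(uniq.shape[1])
    if n == 1:
        return 0
    if n == 2:
        return int((uniq[0] != uniq[1]).sum())
    best = np.inf
    for t in _enumerate_unrooted(n):
        masks = {u: enc[t.labels[u]] for u in t.leaves}
        s = _fitch_score(t, masks, w)
        if s < best:
            best = s
    return int(round(best))


# ---------------------------------------------------------------------------
# rooting and ACCTRAN


@dataclass
class TreeNode:
    name: str | None = None
    children: list = field(default_factory=list)
    length: int = 0
    states: np.ndarray | None = None  # chosen ancestral state per character
    ties: dict = field(default_factory=dict)  # char -> tuple of tied states
    events: list = field(default_factory=list)  # (char, from_state, to_state)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaf_names())
        return out

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class CnaTree:
    """Rooted clonal tree with ACCTRAN branch lengths and events."""

    root: TreeNode
    cells: pd.DataFrame
    segments: pd.DataFrame
    score: int

    def newick(self) -> str:
        def render(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length}"
            inner = ",".join(render(c) for c in node.children)
            return f"({inner}){node.length}:{node.length}"

        inner = ",".join(render(c) for c in self.root.children)
        return f"({inner})root:0;"

    def branch_events_table(self) -> pd.DataFrame:
        rows = []
        idx = 0
        for node in self.root.walk():
            if node is self.root:
                continue
            branch = node.name if node.is_leaf else f"internal_{idx}"
            if not node.is_leaf:
                idx += 1
            for char, s_from, s_to in node.events:
                seg = self.segments.iloc[char]
                rows.append(
                    {
                        "branch": branch,
                        "segment": f"{seg.chrom}:{seg.start_bin}-{seg.end_bin}",
                        "from_state": s_from,
                        "to_state": s_to,
                    }
                )
        return pd.DataFrame(
            rows, columns=["branch", "segment", "from_state", "to_state"]
        )

    @property
    def total_length(self) -> int:
        return sum(n.length for n in self.root.walk())


def root_and_acctran(tree: UnrootedTree, matrix, outgroup) -> CnaTree:
    """Root on the outgroup and reconstruct ancestral states by ACCTRAN.

    The root is placed on the branch separating the outgroup cells; if
    the outgroup shares its (all-neutral) event pattern with other
    zero-event cells, the root becomes the polytomy node those cells
    hang from.  The root state vector is all-neutral, and per-branch
    lengths count the characters changing on that branch.
    """
    rows, ids = _matrix_rows(matrix)
    outgroup = set(outgroup)
    leaf_taxa = set(tree.taxa)
    if not outgroup or not outgroup <= leaf_taxa:
        raise ValueError("outgroup must be a non-empty subset of tree leaves")
    row_of = {c: i for i, c in enumerate(ids)}
    og_rows = [row_of[c] for c in outgroup]
    if np.any(rows[og_rows] != 0):
        warnings.warn(
            "outgroup cells carry non-neutral states; rooting proceeds but "
            "the diploid-root assumption is violated",
            stacklevel=2,
        )

    t = tree.copy()
    node_of = {t.labels[u]: u for u in t.leaves}
    og_nodes = {node_of[c] for c in outgroup}
    # minimal edge side containing every outgroup leaf
    best_edge, best_side = None, None
    for u, v in t.edges():
        for a, b in ((u, v), (v, u)):
            side = t._side(a, b)
            side_leaves = {x for x in side if x in t.labels}
            if og_nodes <= side_leaves:
                if best_side is None or len(side_leaves) < len(best_side):
                    best_edge, best_side = (a, b), side_leaves
    a, b = best_edge
    if best_side == og_nodes:
        root_id = max(t.adj) + 1
        t.adj[a].discard(b)
        t.adj[b].discard(a)
        t.adj[root_id] = {a, b}
        t.adj[a].add(root_id)
        t.adj[b].add(root_id)
    else:
        root_id = a  # outgroup-side endpoint becomes a polytomy root

    # build the rooted node tree (children sorted by smallest leaf name)
    def build(u, parent) -> TreeNode:
        kids = sorted(t.adj[u] - ({parent} if parent is not None else set()))
        if not kids:
            return TreeNode(name=t.labels[u])
        children = [build(k, u) for k in kids]
        children.sort(key=lambda c: min(c.leaf_names()))
        return TreeNode(name=t.labels.get(u), children=children)

    root = build(root_id, None)

    # Fitch downpass
    enc = _encode(rows)
    n_chars = rows.shape[1]
    down: dict[int, np.ndarray] = {}

    def downpass(node: TreeNode) -> np.ndarray:
        if node.is_leaf:
            s = enc[row_of[node.name]]
        else:
            s = None
            for c in node.children:
                cs = downpass(c)
                if s is None:
                    s = cs
                    continue
                inter = s & cs
                s = np.where(inter == 0, s | cs, inter)
        down[id(node)] = s
        return s

    downpass(root)

    # ACCTRAN uppass with the root forced to the all-neutral state
    neutral = np.full(n_chars, _BITS[0], dtype=np.uint8)
    root.states = np.zeros(n_chars, dtype=np.int8)
    root.length = 0

    def pick_states(mask: np.ndarray) -> np.ndarray:
        # preference order on ties: neutral, deletion, amplification
        chosen = np.full(len(mask), 0, dtype=np.int8)
        assigned = np.zeros(len(mask), dtype=bool)
        for b in _TIE_ORDER:
            hit = ((mask & b) > 0) & ~assigned
            chosen[hit] = _STATE_OF_BIT[b]
            assigned |= hit
        return chosen

    def uppass(node: TreeNode, parent_states: np.ndarray):
        for child in node.children:
            cmask = down[id(child)]
            pbits = np.array(
                [_BITS[int(s)] for s in parent_states], dtype=np.uint8
            )
            keep = (cmask & pbits) > 0
            chosen = np.where(keep, parent_states, pick_states(cmask))
            child.states = chosen.astype(np.int8)
            changed = np.where(~keep)[0]
            child.length = int(len(changed))
            child.events = [
                (int(c), int(parent_states[c]), int(chosen[c])) for c in changed
            ]
            child.ties = {
                int(c): tuple(
                    _STATE_OF_BIT[b] for b in (1, 2, 4) if cmask[c] & b
                )
                for c in changed
                if bin(int(cmask[c])).count("1") > 1
            }
            uppass(child, child.states)

    uppass(root, root.states)
    score = sum(n.length for n in root.walk())
    segs = (
        matrix.segments
        if isinstance(matrix, EventMatrix)
        else pd.DataFrame(index=range(n_chars))
    )
    return CnaTree(root=root, cells=_cells_frame(matrix), segments=segs, score=score)


def _cells_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, EventMatrix):
        return matrix.cells.copy()
    raise TypeError("matrix must be an EventMatrix")


# ---------------------------------------------------------------------------
# origin report


def assess_clonal_origin(tree: CnaTree, matrix=None, labels=None) -> dict:
    """Quantify how many independent tumor origins the rooted tree shows.

    A "clonal clade" is a maximal clade whose stem branch carries at
    least one event and whose leaves are all CNA-bearing cells.  The
    number of such clades is the number of inferred origins; the report
    also gives the label composition of the largest clade and a
    label-mixing statistic (fraction of its internal branches whose
    descendants include both green and non-green cells).
    """
    cells = tree.cells
    if labels is None:
        labels = dict(zip(cells["cell_id"], cells["label"]))
    if matrix is not None:
        rows, ids = _matrix_rows(matrix)
        bearing = {c for c, r in zip(ids, rows) if np.any(r != 0)}
    else:
        # reconstruct from leaf branch events: a leaf is CNA-bearing iff
        # its root-path accumulates any non-neutral state
        bearing = set()

        def mark(node: TreeNode, state_nonzero: bool):
            nz = state_nonzero or (
                node.states is not None and bool(np.any(node.states != 0))
            )
            if node.is_leaf:
                if nz:
                    bearing.add(node.name)
            for c in node.children:
                mark(c, False)

        mark(tree.root, False)
    if not bearing:
        return {
            "status": "no tumor lineage detected",
            "n_origins": 0,
            "clonal_clades": [],
        }

    clades: list[TreeNode] = []

    def scan(node: TreeNode):
        for child in node.children:
            leaves = set(child.leaf_names())
            if child.length >= 1 and leaves <= bearing:
                clades.append(child)
            else:
                scan(child)

    scan(tree.root)

    clade_info = []
    for c in clades:
        leaves = c.leaf_names()
        counts = pd.Series([labels.get(l, "?") for l in leaves]).value_counts()
        clade_info.append(
            {
                "n_cells": len(leaves),
                "stem_events": c.length,
                "label_counts": counts.to_dict(),
            }
        )
    report = {
        "status": "ok",
        "n_origins": len(clades),
        "clonal_clades": clade_info,
    }
    if clades:
        largest = max(clades, key=lambda c: len(c.leaf_names()))
        leaves = largest.leaf_names()
        counts = pd.Series([labels.get(l, "?") for l in leaves]).value_counts()
        total = len(leaves)
        internal = [n for n in largest.walk() if not n.is_leaf]
        mixed = 0
        for n in internal:
            labs = {labels.get(l, "?") for l in n.leaf_names()}
            if {"green", "non-green"} <= labs:
                mixed += 1
        report["largest_clade"] = {
            "n_cells": total,
            "stem_events": largest.length,
            "label_counts": counts.to_dict(),
            "label_fractions": {k: v / total for k, v in counts.items()},
            "label_mixing": mixed / len(internal) if internal else 0.0,
        }
    return report
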