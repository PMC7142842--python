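"""Comparing pipeline output against simulated ground truth.

Defines the bookkeeping used to validate parameter recovery: which true
events were re-identified in the called event matrix, how many called
segments have no basis in the truth, and whether the inferred tree's
clone-level topology matches the simulated clone tree (Robinson-Foulds
distance via an independent tree library).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .popseg import EventMatrix
from .simulate import ClonalTruth

__all__ = ["event_recovery", "clone_rf_distance"]


def event_recovery(
    truth: ClonalTruth,
    matrix: EventMatrix,
    min_overlap: float = 0.5,
    carrier_fraction: float = 0.5,
) -> dict:
    """Score called events against the simulated truth.

    A true event is *recovered* when some called segment overlaps at
    least ``min_overlap`` of the event's bins and at least
    ``carrier_fraction`` of the cells carrying the event are called
    with the correct sign there.  A called segment column is *false*
    when it contains a non-neutral call for some cell although no true
    event overlaps it at all.  Sex-chromosome events are excluded (the
    matrix drops them by construction).
    """
    segs = matrix.segments
    ids = matrix.cell_ids
    cell_pos = {c: i for i, c in enumerate(ids)}
    state_truth = truth.event_state_matrix()
    truth_cells = list(truth.cells["cell_id"])
    n_recovered = 0
    n_events = 0
    overlapping_cols: set[int] = set()
    for j, ev in enumerate(truth.events.itertuples()):
        ev_bins = set(range(ev.start_bin, ev.end_bin + 1))
        # columns overlapping this event at all (for the false-call tally)
        touching = []
        for si, seg in enumerate(segs.itertuples()):
            if seg.chrom != ev.chrom:
                continue
            lo = max(seg.start_bin, ev.start_bin)
            hi = min(seg.end_bin, ev.end_bin)
            if hi >= lo:
                touching.append((si, hi - lo + 1))
        for si, _ in touching:
            overlapping_cols.add(si)
        if ev.chrom not in set(segs["chrom"]):
            # event lies on a chromosome absent from the matrix (sex)
            continue
        n_events += 1
        sign = 1 if ev.delta > 0 else -1
        carriers = [
            c
            for c, s in zip(truth_cells, state_truth[:, j])
            if s != 0 and c in cell_pos
        ]
        if not carriers:
            continue
        recovered = False
        for si, ov in touching:
            if ov < min_overlap * len(ev_bins):
                continue
            calls = matrix.states[[cell_pos[c] for c in carriers], si]
            if np.mean(calls == sign) >= carrier_fraction:
                recovered = True
                break
        if recovered:
            n_recovered += 1
    n_false = 0
    for si in range(len(segs)):
        if si in overlapping_cols:
            continue
        if np.any(matrix.states[:, si] != 0):
            n_false += 1
    return {
        "n_events": n_events,
        "n_recovered": n_recovered,
        "recovery_rate": n_recovered / n_events if n_events else np.nan,
        "n_segments": len(segs),
        "n_false_segments": n_false,
        "false_segment_rate": n_false / len(segs) if len(segs) else np.nan,
    }


def clone_rf_distance(truth: ClonalTruth, tree, matrix: EventMatrix) -> int:
    """Robinson-Foulds distance between inferred and true clone topology.

    One representative cell per tumor clone plus one blood cell is
    retained from the inferred (unrooted) tree; the induced topology is
    compared against the simulated clone tree with dendropy's
    symmetric-difference metric on unrooted trees.
    """
    import dendropy

    reps = {}
    for r in truth.cells.itertuples():
        reps.setdefault(r.clone, r.cell_id)
    # map representative cell -> clone taxon name
    rep_to_clone = {cid: clone for clone, cid in reps.items()}
    if "normal" in reps:
        rep_to_clone[reps["normal"]] = "diploid_leaf"

    keep = set(rep_to_clone.values())

    def induced_splits(newick: str, rename: dict) -> set:
        t = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        taxa = keep
        anchor = min(taxa)
        splits = set()
        for node in t.preorder_node_iter():
            if node is t.seed_node or node.is_leaf():
                continue
            side = {
                rename.get(l.taxon.label, l.taxon.label)
                for l in node.leaf_iter()
            } & taxa
            if anchor in side:
                side = taxa - side
            if 2 <= len(side) <= len(taxa) - 2:
                splits.add(frozenset(side))
        return splits

    a = induced_splits(tree.to_newick(), rep_to_clone)
    b = induced_splits(truth.clone_tree_newick(), {})
    return len(a ^ b)
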