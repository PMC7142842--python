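"""Cross-sample analyses: clustering, gene-level copy number, CNA burden.

Cells from several mice are compared on the intersection of their
usable bins by hierarchical clustering of log2 copy-ratio profiles;
gene copy numbers are read off the segment model (cn = 2 x ratio,
length-weighted over the gene interval); and each sample's tree is
summarized by its trunk fraction — the share of total tree length on
the stem of the largest clonal clade — to separate punctuated (early
burst, trunk fraction >= 0.5 by default) from gradual CNA accumulation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .bincounts import RatioProfile
from .phylogeny import CnaTree, assess_clonal_origin
from .popseg import EventMatrix
from .segmentation import SegmentedProfile

__all__ = [
    "read_gene_bed",
    "cluster_profiles",
    "gene_copy_number",
    "cna_burden_summary",
]


def synthetic_gene_table(bins, seed: int = 0, n_genes: int = 12) -> pd.DataFrame:
    """A synthetic stand-in gene list on the simulated genome.

    Real analyses supply their own gene intervals (BED); this helper
    scatters mouse orthologs of commonly HCC-altered genes (symbols
    only — the coordinates are synthetic and tied to the simulated bin
    grid) so gene-level copy-number annotation can be exercised and
    demonstrated without external annotation.
    """
    symbols = [
        "Myc", "Ctnnb1", "Tp53", "Rb1", "Ccnd1", "Met",
        "Axin1", "Arid1a", "Tert", "Vegfa", "Fgf19", "Cdkn2a",
    ][:n_genes]
    rng = np.random.default_rng(seed)
    bt = bins.table
    auto = bt[~bt["chrom"].isin(bins.sex_chroms)]
    rows = []
    idx = rng.choice(auto.index.to_numpy(), size=len(symbols), replace=False)
    for sym, i in zip(symbols, np.sort(idx)):
        start = int(auto.loc[i, "start"]) + int(rng.integers(0, 300_000))
        rows.append(
            {
                "chrom": auto.loc[i, "chrom"],
                "start": start,
                "end": start + int(rng.integers(20_000, 150_000)),
                "gene": sym,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["chrom", "start"])
        .reset_index(drop=True)
    )


def read_gene_bed(path) -> pd.DataFrame:
    """Read a gene interval list (BED: chrom, start, end, symbol)."""
    genes = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene"],
        dtype={"chrom": str},
    )
    if (genes["end"] <= genes["start"]).any():
        raise ValueError("malformed gene interval (end <= start)")
    return genes.sort_values(["chrom", "start"]).reset_index(drop=True)


def cluster_profiles(
    profiles: list[RatioProfile],
    linkage_method: str = "average",
    k_neighbors: int = 5,
) -> dict:
    """Hierarchically cluster cells from several samples.

    Profiles are joined on the intersection of usable bins; distances
    are Euclidean on log2 ratios.  Returns the leaf ordering, the
    linkage matrix, and a per-cell sample-purity score: the fraction of
    each cell's k nearest neighbors that come from the same mouse.
    """
    if not profiles:
        raise ValueError("no profiles given")
    common = profiles[0].usable.copy()
    for p in profiles[1:]:
        if p.bins.n_bins != profiles[0].bins.n_bins:
            raise ValueError("profiles must share the same bin set")
        common &= p.usable
    X_parts, mouse, cell_ids = [], [], []
    for p in profiles:
        X_parts.append(p.ratios[common, :].T)
        mouse.extend(p.cells["mouse"])
        cell_ids.extend(p.cell_ids)
    X = np.vstack(X_parts)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 cells to cluster")
    L = np.log2(np.maximum(X, 2 ** -8))
    D = pdist(L, metric="euclidean")
    Z = hierarchy.linkage(D, method=linkage_method)
    order = list(hierarchy.leaves_list(Z))
    Dm = squareform(D)
    np.fill_diagonal(Dm, np.inf)
    mouse = np.asarray(mouse)
    k = min(k_neighbors, X.shape[0] - 1)
    purity = np.empty(X.shape[0])
    for i in range(X.shape[0]):
        nn = np.argsort(Dm[i], kind="stable")[:k]
        purity[i] = float(np.mean(mouse[nn] == mouse[i]))
    return {
        "cell_ids": cell_ids,
        "mouse": list(mouse),
        "order": order,
        "linkage": Z,
        "purity": purity,
        "log2_matrix": L,
    }


def save_cluster_heatmap(result: dict, path) -> None:
    """Render the clustered log2-ratio heatmap to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = result["order"]
    L = result["log2_matrix"][order]
    fig, ax = plt.subplots(figsize=(10, 0.2 * len(order) + 2))
    im = ax.imshow(L, aspect="auto", cmap="RdBu_r", vmin=-2, vmax=2)
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels([result["cell_ids"][i] for i in order], fontsize=4)
    ax.set_xlabel("bin")
    fig.colorbar(im, ax=ax, label="log2 copy ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def gene_copy_number(
    seg: SegmentedProfile, genes: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene, per-cell copy number from the segment model.

    cn(gene, cell) = 2 x length-weighted mean segment ratio over the
    usable bins the gene overlaps; genes touching no usable bin get NaN.
    Returns a genes x cells table.
    """
    bins = seg.bins
    bt = bins.table
    usable = bins.usable
    if (genes["end"] <= genes["start"]).any():
        raise ValueError("malformed gene interval (end <= start)")
    cells = list(dict.fromkeys(seg.segments["cell_id"]))
    # bin -> (cell -> ratio) from segments
    ratio_of = {c: np.full(bins.n_bins, np.nan) for c in cells}
    for r in seg.segments.itertuples():
        ratio_of[r.cell_id][r.start_bin : r.end_bin + 1] = r.mean_ratio
    out = np.full((len(genes), len(cells)), np.nan)
    starts = bt["start"].to_numpy()
    ends = bt["end"].to_numpy()
    chroms = bt["chrom"].to_numpy()
    for gi, g in enumerate(genes.itertuples()):
        on = (chroms == g.chrom) & (ends > g.start) & (starts < g.end) & usable
        idx = np.where(on)[0]
        if len(idx) == 0:
            continue
        w = np.minimum(ends[idx], g.end) - np.maximum(starts[idx], g.start)
        for ci, cell in enumerate(cells):
            r = ratio_of[cell][idx]
            ok = ~np.isnan(r)
            if ok.any():
                out[gi, ci] = 2.0 * float(np.average(r[ok], weights=w[ok]))
    return pd.DataFrame(out, index=genes["gene"], columns=cells)


def cna_burden_summary(
    samples: dict,
    punctuated_threshold: float = 0.5,
) -> pd.DataFrame:
    """Trunk/branch event-burden summary per sample.

    ``samples`` maps sample name to ``(CnaTree, EventMatrix)``.  For
    each sample: mean events per cell (row sums of |event matrix|),
    trunk fraction = stem length of the largest clonal clade divided by
    total tree length, and the punctuated/gradual flag (trunk fraction
    >= threshold -> "punctuated-like").  Zero-event samples report a
    missing trunk fraction.
    """
    rows = []
    for name, (tree, matrix) in samples.items():
        if tree.root is None:
            raise ValueError(f"{name}: tree is not rooted")
        burden = np.abs(matrix.states).sum(axis=1)
        total_len = tree.total_length
        if total_len == 0:
            trunk_frac = np.nan
            mode = "no-events"
        else:
            report = assess_clonal_origin(tree, matrix)
            stem = (
                report["largest_clade"]["stem_events"]
                if report.get("largest_clade")
                else 0
            )
            trunk_frac = stem / total_len
            mode = (
                "punctuated-like"
                if trunk_frac >= punctuated_threshold
                else "gradual-like"
            )
        rows.append(
            {
                "sample": name,
                "n_cells": len(matrix.cells),
                "mean_events_per_cell": float(burden.mean()),
                "trunk_fraction": trunk_frac,
                "evolution_mode": mode,
            }
        )
    return pd.DataFrame(rows)
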