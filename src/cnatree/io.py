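"""Readers and writers for the pipeline's on-disk formats.

All coordinates are 0-based half-open internally; SEG output follows
the 1-based inclusive convention, with the conversion applied at the
boundary.  Every writer has a paired reader that reproduces the data
model (round-trip equality).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bincounts import BinCountMatrix, RatioProfile
from .genome import GenomeBins
from .popseg import EventMatrix
from .segmentation import SegmentedProfile

__all__ = [
    "write_counts_tsv",
    "read_counts_tsv",
    "write_ratio_tsv",
    "read_ratio_tsv",
    "write_seg",
    "read_seg",
    "write_event_matrix_tsv",
    "read_event_matrix_tsv",
    "write_qc_report",
    "write_json",
    "read_json",
]

_META_COLS = ["chrom", "start", "end"]


def _cells_from_columns(cols, cells: pd.DataFrame | None) -> pd.DataFrame:
    if cells is not None:
        return cells
    return pd.DataFrame({"cell_id": list(cols), "label": "green", "mouse": "NA"})


def write_counts_tsv(path, counts: BinCountMatrix) -> None:
    """Bins as rows (chrom, start, end), one integer column per cell."""
    df = counts.bins.table[_META_COLS].copy()
    for i, cid in enumerate(counts.cell_ids):
        df[cid] = counts.counts[:, i]
    df.to_csv(path, sep="\t", index=False)


def read_counts_tsv(
    path, bins: GenomeBins, cells: pd.DataFrame | None = None
) -> BinCountMatrix:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"count matrix not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    cell_cols = [c for c in df.columns if c not in _META_COLS]
    if (df["chrom"].to_numpy() != bins.table["chrom"].to_numpy()).any() or (
        df["start"].to_numpy() != bins.table["start"].to_numpy()
    ).any():
        raise ValueError("count matrix bins do not match the bin definitions")
    return BinCountMatrix(
        bins=bins,
        counts=df[cell_cols].to_numpy(np.int64),
        cells=_cells_from_columns(cell_cols, cells),
    )


def write_ratio_tsv(path, profile: RatioProfile, log2: bool = False) -> None:
    """Ratio matrix TSV; log2-transformed when requested (display scale)."""
    df = profile.bins.table[_META_COLS].copy()
    vals = profile.ratios
    if log2:
        with np.errstate(divide="ignore"):
            vals = np.log2(np.maximum(vals, 0) + 1e-12)
    for i, cid in enumerate(profile.cell_ids):
        df[cid] = vals[:, i]
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_ratio_tsv(
    path, bins: GenomeBins, cells: pd.DataFrame | None = None
) -> RatioProfile:
    df = pd.read_csv(Path(path), sep="\t", dtype={"chrom": str})
    cell_cols = [c for c in df.columns if c not in _META_COLS]
    return RatioProfile(
        bins=bins,
        ratios=df[cell_cols].to_numpy(float),
        cells=_cells_from_columns(cell_cols, cells),
    )


def write_seg(path, seg: SegmentedProfile) -> None:
    """SEG format: sample, chrom, start/end (1-based inclusive bp),
    num_mark, seg_mean as log2 ratio."""
    bt = seg.bins.table
    starts = bt["start"].to_numpy()
    ends = bt["end"].to_numpy()
    rows = []
    for r in seg.segments.itertuples():
        rows.append(
            {
                "ID": r.cell_id,
                "chrom": r.chrom,
                "loc.start": int(starts[r.start_bin]) + 1,
                "loc.end": int(ends[r.end_bin]),
                "num.mark": r.n_bins,
                "seg.mean": np.log2(max(r.mean_ratio, 1e-12)),
            }
        )
    pd.DataFrame(
        rows, columns=["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_seg(path, bins: GenomeBins, provenance: str = "per-cell") -> SegmentedProfile:
    df = pd.read_csv(Path(path), sep="\t", dtype={"chrom": str})
    bt = bins.table
    rows = []
    for r in df.itertuples():
        chrom_mask = bt["chrom"] == r.chrom
        start0 = getattr(r, "_3") - 1  # loc.start back to 0-based
        end_bp = getattr(r, "_4")
        sub = bt[chrom_mask]
        start_bin = int(sub.index[sub["start"] == start0][0])
        end_bin = int(sub.index[sub["end"] == end_bp][0])
        rows.append(
            {
                "cell_id": r.ID,
                "chrom": r.chrom,
                "start_bin": start_bin,
                "end_bin": end_bin,
                "n_bins": int(getattr(r, "_5")),
                "mean_ratio": float(2 ** getattr(r, "_6")),
            }
        )
    seg = pd.DataFrame(
        rows,
        columns=["cell_id", "chrom", "start_bin", "end_bin", "n_bins", "mean_ratio"],
    )
    return SegmentedProfile(segments=seg, bins=bins, provenance=provenance)


def write_event_matrix_tsv(path, matrix: EventMatrix) -> None:
    """Cells as rows, segments as columns, entries -1/0/1."""
    matrix.to_frame().to_csv(path, sep="\t", index_label="cell_id")


def read_event_matrix_tsv(path, cells: pd.DataFrame | None = None) -> EventMatrix:
    df = pd.read_csv(Path(path), sep="\t", index_col="cell_id")
    seg_rows = []
    for col in df.columns:
        chrom, span = col.split(":")
        a, b = span.split("-")
        seg_rows.append(
            {
                "chrom": chrom,
                "start_bin": int(a),
                "end_bin": int(b),
                "n_bins": int(b) - int(a) + 1,
                "start_bp": -1,
                "end_bp": -1,
            }
        )
    if cells is None:
        cells = pd.DataFrame(
            {"cell_id": list(df.index), "label": "green", "mouse": "NA"}
        )
    return EventMatrix(
        states=df.to_numpy(np.int8),
        segments=pd.DataFrame(seg_rows),
        cells=cells,
    )


def write_qc_report(path, counts: BinCountMatrix, profile: RatioProfile) -> None:
    """Per-cell QC: total reads and the MAD of usable autosomal ratios."""
    mask = profile.usable & profile.bins.autosomal
    rows = []
    for i, cid in enumerate(counts.cell_ids):
        r = profile.ratios[mask, i]
        r = r[~np.isnan(r)]
        mad = float(np.median(np.abs(r - np.median(r)))) if len(r) else np.nan
        rows.append(
            {
                "cell_id": cid,
                "total_reads": int(counts.counts[:, i].sum()),
                "ratio_mad": mad,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
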