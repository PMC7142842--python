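"""From aligned reads or raw bin counts to GC-normalized copy-number ratios.

The canonical input is a bins x cells integer count matrix (one column
per single cell); BAM/SAM ingestion is a thin optional front end.  The
processing follows the standard low-pass single-cell CNV recipe:
drop duplicate/low-quality reads while counting (mapping quality < 40
by default), mask aberrant bins using normal reference cells, remove
the GC-content coverage bias with LOESS, and rescale each cell so the
median usable autosomal ratio is 1 (the diploid baseline — copy number
= 2 x ratio).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genome import GenomeBins

__all__ = [
    "BinCountMatrix",
    "RatioProfile",
    "count_reads_in_bins",
    "filter_aberrant_bins",
    "gc_normalize",
]

logger = logging.getLogger(__name__)


@dataclass
class BinCountMatrix:
    """Raw per-cell read counts per bin plus cell metadata."""

    bins: GenomeBins
    counts: np.ndarray  # (n_bins, n_cells) int
    cells: pd.DataFrame  # cell_id, label, mouse[, clone]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (bins x cells)")
        if self.counts.shape[0] != self.bins.n_bins:
            raise ValueError("counts row count != number of bins")
        if self.counts.shape[1] != len(self.cells):
            raise ValueError("counts column count != number of cells")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        ids = self.cells["cell_id"]
        if ids.duplicated().any():
            raise ValueError("cell ids must be unique")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.cells["cell_id"])

    def column(self, cell_id: str) -> np.ndarray:
        return self.counts[:, self.cell_ids.index(cell_id)]


@dataclass
class RatioProfile:
    """GC-normalized copy-number ratios (1.0 = diploid); NaN at masked bins."""

    bins: GenomeBins
    ratios: np.ndarray  # (n_bins, n_cells) float, NaN where unusable
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, float)
        if self.ratios.shape != (self.bins.n_bins, len(self.cells)):
            raise ValueError("ratio matrix shape mismatch")
        with np.errstate(invalid="ignore"):
            if np.any(self.ratios < 0):
                raise ValueError("ratios must be non-negative")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.cells["cell_id"])

    @property
    def usable(self) -> np.ndarray:
        return self.bins.usable


def count_reads_in_bins(
    alignment_sources,
    bins: GenomeBins,
    min_mapping_quality: int = 40,
    drop_duplicates: bool = True,
    cells: pd.DataFrame | None = None,
) -> BinCountMatrix:
    """Count aligned reads per bin for one or more single-cell SAM/BAM files.

    Each file is one cell (column).  A record is counted in exactly one
    bin, chosen by its leftmost aligned position; unmapped records,
    records below ``min_mapping_quality`` and (optionally) records
    carrying the PCR-duplicate flag are dropped.  Records on
    chromosomes absent from ``bins`` are skipped and tallied to the log.
    """
    import pysam
    from pathlib import Path

    if isinstance(alignment_sources, (str, Path)):
        alignment_sources = [alignment_sources]
    slices = bins.chrom_slices()
    chrom_start0 = {c: sl.start for c, sl in slices.items()}
    chrom_nbins = {c: sl.stop - sl.start for c, sl in slices.items()}
    counts = np.zeros((bins.n_bins, len(alignment_sources)), dtype=np.int64)
    for ci, src in enumerate(alignment_sources):
        skipped_chrom = 0
        with pysam.AlignmentFile(str(src), check_sq=False) as af:
            for rec in af.fetch(until_eof=True):
                if rec.is_unmapped:
                    continue
                if rec.mapping_quality < min_mapping_quality:
                    continue
                if drop_duplicates and rec.is_duplicate:
                    continue
                chrom = rec.reference_name
                if chrom not in chrom_start0:
                    skipped_chrom += 1
                    continue
                idx = rec.reference_start // bins.bin_size
                if idx >= chrom_nbins[chrom]:
                    skipped_chrom += 1
                    continue
                counts[chrom_start0[chrom] + idx, ci] += 1
        if skipped_chrom:
            logger.info(
                "%s: skipped %d records on chromosomes outside the bin set",
                src,
                skipped_chrom,
            )
    if cells is None:
        cells = pd.DataFrame(
            {
                "cell_id": [Path(str(s)).stem for s in alignment_sources],
                "label": "green",
                "mouse": "NA",
            }
        )
    return BinCountMatrix(bins=bins, counts=counts, cells=cells)


def filter_aberrant_bins(
    counts: BinCountMatrix,
    reference_cells=None,
    mad_multiplier: float = 5.0,
) -> GenomeBins:
    """Mask systematically aberrant bins; returns bins with updated mask.

    Coverage in each reference (normal diploid) cell is scaled to mean 1
    over currently-usable bins; a bin is masked when its median scaled
    coverage across references is zero, or deviates from its
    chromosome's median by more than ``mad_multiplier`` (scaled) median
    absolute deviations.  Without reference cells all cells are pooled.
    """
    ids = counts.cell_ids
    if reference_cells:
        ref_idx = [ids.index(c) for c in reference_cells]
    else:
        ref_idx = list(range(len(ids)))
    sub = counts.counts[:, ref_idx].astype(float)
    usable = counts.bins.usable.copy()
    # per-cell depth scaling on currently usable bins
    depth = sub[usable].mean(axis=0)
    depth[depth == 0] = 1.0
    norm = sub / depth
    med = np.median(norm, axis=1)

    new_usable = usable.copy()
    for chrom, sl in counts.bins.chrom_slices().items():
        m = med[sl]
        u = usable[sl]
        if not u.any():
            continue
        center = np.median(m[u])
        mad = 1.4826 * np.median(np.abs(m[u] - center))
        bad = (m == 0) | ((mad > 0) & (np.abs(m - center) > mad_multiplier * mad))
        block = new_usable[sl]
        block[bad] = False
        new_usable[sl] = block
    if not new_usable.any():
        raise ValueError("no usable bins left after aberrant-bin filtering")
    return counts.bins.with_usable(new_usable)


def _loess_fit(y: np.ndarray, gc: np.ndarray, span: float) -> np.ndarray:
    """LOESS fit of counts on GC, evaluated at the input GC values."""
    fitted = lowess(y, gc, frac=span, return_sorted=False)
    return np.asarray(fitted, float)


def gc_normalize(
    counts: BinCountMatrix,
    bins: GenomeBins | None = None,
    loess_span: float = 0.3,
    min_usable_bins: int = 100,
) -> RatioProfile:
    """LOESS-correct the GC coverage bias and rescale to a diploid baseline.

    Per cell: fit a locally weighted regression of count on GC over the
    usable autosomal bins, divide counts by the fitted curve (sex-
    chromosome bins use the interpolated curve), then rescale so the
    median usable autosomal ratio equals 1.  The result is invariant to
    any positive scaling of a cell's counts.
    """
    if bins is None:
        bins = counts.bins
    usable = bins.usable
    fit_mask = usable & bins.autosomal
    n_fit = int(fit_mask.sum())
    if n_fit == 0:
        raise ValueError("no usable autosomal bins")
    if n_fit < min_usable_bins:
        warnings.warn(
            f"only {n_fit} usable autosomal bins (< {min_usable_bins}); "
            "GC fit may be unstable",
            stacklevel=2,
        )
    gc = bins.gc
    ratios = np.full(counts.counts.shape, np.nan)
    degenerate = np.ptp(gc[fit_mask]) == 0
    if degenerate:
        warnings.warn(
            "degenerate GC (all equal); skipping LOESS, scaling by mean",
            stacklevel=2,
        )
    order = np.argsort(gc[fit_mask], kind="stable")
    for ci in range(counts.counts.shape[1]):
        y = counts.counts[:, ci].astype(float)
        if degenerate:
            fit_all = np.full(bins.n_bins, max(y[fit_mask].mean(), 1e-12))
        else:
            fitted = _loess_fit(y[fit_mask], gc[fit_mask], loess_span)
            # evaluate the curve at every usable bin's GC (incl. sex chrom)
            fit_all = np.interp(
                gc, gc[fit_mask][order], fitted[order]
            )
        fit_all = np.maximum(fit_all, 1e-12)
        r = np.where(usable, y / fit_all, np.nan)
        scale = np.nanmedian(r[fit_mask])
        if not np.isfinite(scale) or scale <= 0:
            scale = 1.0
        ratios[:, ci] = r / scale
    return RatioProfile(bins=bins, ratios=ratios, cells=counts.cells.copy())
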