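"""Per-cell segmentation: circular binary segmentation (CBS) + MergeLevels.

CBS recursively tests, on each chromosome, the best "circular" split of
the copy-ratio series — the arc maximizing a two-sample mean-difference
statistic over all admissible (i, j) arc boundaries — against a
permutation null, accepting splits with permutation p < alpha
(default 0.01, the standard setting for low-pass single-cell data).
Accepted splits are then pruned: a boundary is undone when the mean
difference between the two segments it separates falls below
``undo_prune_sd`` profile-noise standard deviations, the noise SD being
the robust first-difference estimate
``1.4826 * median|x_{t+1} - x_t| / sqrt(2)``.

MergeLevels collapses adjacent segments whose member-bin distributions
do not differ by a rank-sum test, closest means first, until every
remaining adjacent pair differs significantly.

Segmentation runs on linear ratios (not log2) so segment means compare
directly to the 1.4/0.6 amplification/deletion cutoffs used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bincounts import RatioProfile
from .genome import GenomeBins

__all__ = ["CbsParams", "SegmentedProfile", "cbs_segment", "merge_levels"]


@dataclass
class CbsParams:
    alpha: float = 0.01
    n_permutations: int = 1000
    undo_prune_sd: float = 0.05
    min_width: int = 2
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if self.min_width < 1:
            raise ValueError("min_width must be >= 1")
        if self.undo_prune_sd < 0:
            raise ValueError("undo_prune_sd must be >= 0")


@dataclass
class SegmentedProfile:
    """Piecewise-constant fit: ordered segments per cell.

    ``segments`` columns: cell_id, chrom, start_bin, end_bin (global bin
    indices, inclusive, referring to usable bins), n_bins (number of
    usable member bins), mean_ratio.  Segment means always equal the
    arithmetic mean of their member-bin ratios.
    """

    segments: pd.DataFrame
    bins: GenomeBins
    provenance: str = "per-cell"

    def for_cell(self, cell_id: str) -> pd.DataFrame:
        return self.segments[self.segments["cell_id"] == cell_id]

    @property
    def n_segments(self) -> int:
        return len(self.segments)


# ---------------------------------------------------------------------------
# max arc statistic

_PAIR_CACHE: dict = {}


def _arc_pairs(n: int, min_width: int):
    """Admissible arc boundaries (i, j) and their pooled-size coefficient."""
    key = (n, min_width)
    if key in _PAIR_CACHE:
        return _PAIR_CACHE[key]
    ii, jj = [], []
    for i in range(0, n):
        if i != 0 and i < min_width:
            continue
        for j in range(i + min_width, n + 1):
            if j != n and n - j < min_width:
                continue
            if i == 0 and j == n:
                continue
            ii.append(i)
            jj.append(j)
    I = np.asarray(ii, np.int64)
    J = np.asarray(jj, np.int64)
    k = J - I
    coef = 1.0 / np.sqrt(1.0 / k + 1.0 / (n - k))
    out = (I, J, k, coef)
    if n <= 1200:
        _PAIR_CACHE[key] = out
    return out


def _max_arc_stat(x: np.ndarray, min_width: int):
    """Best circular split of ``x``: (statistic, i, j).

    The statistic is |mean(arc) - mean(complement)| scaled by
    1/sqrt(1/k + 1/(n-k)); its permutation distribution supplies the
    significance test, so the (common) noise SD cancels.
    """
    n = len(x)
    I, J, k, coef = _arc_pairs(n, min_width)
    if len(I) == 0:
        return 0.0, 0, n
    S = np.concatenate(([0.0], np.cumsum(x)))
    T = S[n]
    sum_in = S[J] - S[I]
    stat = np.abs(sum_in / k - (T - sum_in) / (n - k)) * coef
    b = int(np.argmax(stat))
    return float(stat[b]), int(I[b]), int(J[b])


def _permutation_pvalue(
    x: np.ndarray,
    observed: float,
    params: CbsParams,
    rng: np.random.Generator,
) -> float:
    """Permutation p-value for the observed max arc statistic.

    Early-stops once enough permuted statistics exceed the observed one
    that p >= alpha is certain.
    """
    n_perm = params.n_permutations
    stop_at = int(np.ceil(params.alpha * (n_perm + 1)))
    exceed = 0
    done = 0
    block = 50
    y = x.copy()
    while done < n_perm:
        m = min(block, n_perm - done)
        for _ in range(m):
            rng.shuffle(y)
            s, _, _ = _max_arc_stat(y, params.min_width)
            if s >= observed:
                exceed += 1
        done += m
        if exceed >= stop_at:
            break
    return (1 + exceed) / (1 + done)


def _segment_chromosome(
    x: np.ndarray, params: CbsParams, rng: np.random.Generator
) -> list[int]:
    """Recursive CBS on one chromosome; returns interior boundaries."""
    boundaries: set[int] = set()

    stack = [(0, len(x))]
    while stack:
        lo, hi = stack.pop()
        n = hi - lo
        if n < 2 * params.min_width:
            continue
        seg = x[lo:hi]
        if np.ptp(seg) == 0:
            continue
        stat, i, j = _max_arc_stat(seg, params.min_width)
        if stat <= 0:
            continue
        p = _permutation_pvalue(seg, stat, params, rng)
        if p < params.alpha:
            cuts = [c for c in (i, j) if 0 < c < n]
            pieces = sorted({0, *cuts, n})
            for c in cuts:
                boundaries.add(lo + c)
            for a, b in zip(pieces[:-1], pieces[1:]):
                stack.append((lo + a, lo + b))
    return sorted(boundaries)


def _undo_prune(
    x: np.ndarray, boundaries: list[int], params: CbsParams
) -> list[int]:
    """Undo splits whose between-segment mean difference is sub-noise."""
    if not boundaries:
        return boundaries
    diffs = np.diff(x)
    sd = 1.4826 * np.median(np.abs(diffs)) / np.sqrt(2.0) if len(diffs) else 0.0
    thr = params.undo_prune_sd * sd
    bounds = [0, *boundaries, len(x)]
    while len(bounds) > 2:
        means = [x[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])]
        gaps = np.abs(np.diff(means))
        k = int(np.argmin(gaps))
        if gaps[k] < thr:
            del bounds[k + 1]
        else:
            break
    return bounds[1:-1]


def cbs_segment(profile: RatioProfile, params: CbsParams | None = None) -> SegmentedProfile:
    """Segment every cell's ratio profile chromosome by chromosome."""
    params = params or CbsParams()
    params.validate()
    usable = profile.usable
    if profile.ratios.size == 0 or not usable.any():
        raise ValueError("empty ratio profile")
    rows = []
    slices = profile.bins.chrom_slices()
    chroms = profile.bins.table["chrom"].to_numpy()
    for ci, cell in enumerate(profile.cell_ids):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(params.seed), ci])
        )
        for chrom, sl in slices.items():
            mask = usable[sl.start : sl.stop]
            if not mask.any():
                continue
            gidx = np.arange(sl.start, sl.stop)[mask]
            x = profile.ratios[gidx, ci]
            if np.isnan(x).any():
                raise ValueError(
                    f"NaN ratios in usable bins ({cell}, {chrom}); "
                    "mask them before segmentation"
                )
            if len(x) < 2 * params.min_width:
                bnds: list[int] = []
            else:
                bnds = _segment_chromosome(x, params, rng)
                bnds = _undo_prune(x, bnds, params)
            edges = [0, *bnds, len(x)]
            for a, b in zip(edges[:-1], edges[1:]):
                rows.append(
                    {
                        "cell_id": cell,
                        "chrom": chrom,
                        "start_bin": int(gidx[a]),
                        "end_bin": int(gidx[b - 1]),
                        "n_bins": b - a,
                        "mean_ratio": float(x[a:b].mean()),
                    }
                )
    seg = pd.DataFrame(
        rows,
        columns=["cell_id", "chrom", "start_bin", "end_bin", "n_bins", "mean_ratio"],
    )
    return SegmentedProfile(segments=seg, bins=profile.bins, provenance="per-cell")


# ---------------------------------------------------------------------------
# MergeLevels


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def merge_levels(
    seg: SegmentedProfile,
    profile: RatioProfile,
    merge_p_threshold: float = 1e-4,
) -> SegmentedProfile:
    """Merge adjacent segments whose bin values are statistically level.

    Adjacent pairs (within a chromosome) are visited in order of
    increasing mean difference; a pair whose member-bin ratios do not
    differ by a two-sided rank-sum test (p >= threshold) is merged and
    the scan restarts, until every remaining adjacent pair differs.
    Never increases the segment count and is idempotent on its output.
    """
    if not 0 < merge_p_threshold < 1:
        raise ValueError("merge_p_threshold must be in (0, 1)")
    usable = profile.usable
    out_rows = []
    for ci, cell in enumerate(profile.cell_ids):
        sub = seg.for_cell(cell)
        for chrom in profile.bins.chroms:
            pieces = sub[sub["chrom"] == chrom].sort_values("start_bin")
            if pieces.empty:
                continue
            segs = []
            for r in pieces.itertuples():
                gidx = np.arange(r.start_bin, r.end_bin + 1)
                gidx = gidx[usable[gidx]]
                segs.append([r.start_bin, r.end_bin, profile.ratios[gidx, ci]])
            merged = True
            while merged and len(segs) > 1:
                merged = False
                gaps = [
                    abs(segs[k][2].mean() - segs[k + 1][2].mean())
                    for k in range(len(segs) - 1)
                ]
                for k in np.argsort(gaps, kind="stable"):
                    k = int(k)
                    if _ranksum_p(segs[k][2], segs[k + 1][2]) >= merge_p_threshold:
                        segs[k] = [
                            segs[k][0],
                            segs[k + 1][1],
                            np.concatenate([segs[k][2], segs[k + 1][2]]),
                        ]
                        del segs[k + 1]
                        merged = True
                        break
            for s in segs:
                out_rows.append(
                    {
                        "cell_id": cell,
                        "chrom": chrom,
                        "start_bin": int(s[0]),
                        "end_bin": int(s[1]),
                        "n_bins": len(s[2]),
                        "mean_ratio": float(s[2].mean()),
                    }
                )
    out = pd.DataFrame(
        out_rows,
        columns=["cell_id", "chrom", "start_bin", "end_bin", "n_bins", "mean_ratio"],
    )
    return SegmentedProfile(segments=out, bins=seg.bins, provenance=seg.provenance)
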