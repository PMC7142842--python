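"""Joint (population) segmentation and trinary CNA event calling.

All cells of a sample are segmented together under a single shared
breakpoint set per chromosome, minimizing

    sum_cells SSE(per-cell piecewise-constant fit)  +  gamma * #breakpoints

by exact dynamic programming (gamma = 20 by default, the standard
penalty for this class of multi-sample piecewise-constant fits).
Shared segments shorter than ``min_bins`` (10) are removed, each
remaining (cell, segment) mean ratio is classified as amplification
(ratio >= 1.4), deletion (<= 0.6) or neutral diploid (0.7 < ratio <
1.3, i.e. copy number between 1.4 and 2.6); ratios in the boundary
bands [0.6, 0.7] and [1.3, 1.4] are ambiguous and resolved to the most
probable state by a 3-component Gaussian Bayes classifier.  Events on
sex chromosomes are dropped from the final cells x segments matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bincounts import RatioProfile
from .genome import GenomeBins
from .segmentation import SegmentedProfile

__all__ = [
    "AMBIGUOUS",
    "EventCallConfig",
    "EventMatrix",
    "multisample_segment",
    "filter_short_segments",
    "call_event_state",
    "bayesian_resolve",
    "build_event_matrix",
    "call_events",
]

AMBIGUOUS = "ambiguous"


@dataclass
class EventCallConfig:
    """Penalty, cutoffs and Bayes model for event calling.

    The cutoffs are the published decision boundaries: amplification at
    copy-number ratio >= 1.4 and deletion at <= 0.6; ratios strictly
    inside (0.7, 1.3) — copy number 1.4 to 2.6 — are neutral diploid,
    and the closed boundary bands are ambiguous.  State means default to
    ratios of copy numbers 1, 2 and 3.
    """

    gamma: float = 20.0
    min_bins: int = 10
    amp_cutoff: float = 1.4
    del_cutoff: float = 0.6
    neutral_high: float = 1.3
    neutral_low: float = 0.7
    state_means: tuple = (0.5, 1.0, 1.5)  # deletion, neutral, amplification
    state_sd: float | None = None  # estimated from neutral segments if None
    priors: tuple | None = None  # empirical if None
    dp_max_bins: int = 1000

    def validate(self) -> None:
        if not (
            self.del_cutoff < self.neutral_low < self.neutral_high < self.amp_cutoff
        ):
            raise ValueError(
                "cutoffs must satisfy del < neutral_low < neutral_high < amp"
            )
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.min_bins < 1:
            raise ValueError("min_bins must be >= 1")


@dataclass
class EventMatrix:
    """Cells x autosomal segments trinary matrix (-1 del, 0 neutral, +1 amp)."""

    states: np.ndarray  # (n_cells, n_segments) int8
    segments: pd.DataFrame  # chrom, start_bin, end_bin, n_bins, start_bp, end_bp
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, np.int8)
        if self.states.shape != (len(self.cells), len(self.segments)):
            raise ValueError("event matrix shape mismatch")
        if not np.isin(self.states, (-1, 0, 1)).all():
            raise ValueError("event states must be in {-1, 0, +1}")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.cells["cell_id"])

    def to_frame(self) -> pd.DataFrame:
        cols = [
            f"{r.chrom}:{r.start_bin}-{r.end_bin}"
            for r in self.segments.itertuples()
        ]
        return pd.DataFrame(self.states, index=self.cell_ids, columns=cols)


# ---------------------------------------------------------------------------
# joint segmentation


def _segment_cost_components(R: np.ndarray):
    """Cumulative sums used by the shared-breakpoint DP.

    R is (n_bins, n_cells).  cost(i, j) of fitting each cell's own mean
    on [i, j) is  sum_c [QQ(j)-QQ(i)] - sum_c (S_c(j)-S_c(i))^2 / (j-i).
    """
    S = np.vstack([np.zeros(R.shape[1]), np.cumsum(R, axis=0)])  # (n+1, c)
    QQ = np.concatenate(([0.0], np.cumsum((R**2).sum(axis=1))))  # (n+1,)
    return S, QQ


def _joint_dp(R: np.ndarray, gamma: float):
    """Exact DP over shared breakpoints for one chromosome.

    Returns (interior breakpoints, objective SSE + gamma * #breakpoints).
    Ties favor the later predecessor, i.e. more/later breakpoints, so
    gamma = 0 on any data yields the interpolating fit.
    """
    n = R.shape[0]
    S, QQ = _segment_cost_components(R)
    f = np.full(n + 1, np.inf)
    f[0] = 0.0
    prev = np.zeros(n + 1, dtype=np.int64)
    for j in range(1, n + 1):
        i = np.arange(j)
        width = j - i
        sse = (QQ[j] - QQ[i]) - (((S[j] - S[i]) ** 2).sum(axis=1) / width)
        cand = f[:j] + sse + gamma
        b = len(cand) - 1 - int(np.argmin(cand[::-1]))  # last argmin
        f[j] = cand[b]
        prev[j] = b
    cuts = []
    j = n
    while j > 0:
        i = int(prev[j])
        if i > 0:
            cuts.append(i)
        j = i
    cuts.sort()
    return cuts, float(f[n] - gamma) if n > 0 else 0.0


def _joint_dp_coarse(R: np.ndarray, gamma: float, max_bins: int):
    """Coarse-to-fine heuristic for chromosomes above the exact-DP cutover.

    Bins are grouped into blocks, the DP runs on block means (weighted),
    and each coarse breakpoint is then refined within its neighborhood
    by exact local search on the full-resolution objective.
    """
    n = R.shape[0]
    block = int(np.ceil(n / max_bins))
    nb = int(np.ceil(n / block))
    Rb = np.add.reduceat(R, np.arange(0, n, block), axis=0) / np.minimum(
        block, n - np.arange(0, n, block)
    ).reshape(-1, 1)
    cuts_b, _ = _joint_dp(Rb * np.sqrt(block), gamma)  # weight blocks by size
    S, QQ = _segment_cost_components(R)

    def local_cost(a, m, b):
        i = np.array([a, m])
        j = np.array([m, b])
        w = j - i
        return float(
            ((QQ[j] - QQ[i]) - ((S[j] - S[i]) ** 2).sum(axis=1) / w).sum()
        )

    cuts = sorted(min(c * block, n - 1) for c in cuts_b)
    refined = []
    bounds = [0, *cuts, n]
    for k in range(1, len(bounds) - 1):
        lo = bounds[k - 1] + 1
        hi = bounds[k + 1] - 1
        lo = max(lo, bounds[k] - 2 * block)
        hi = min(hi, bounds[k] + 2 * block)
        best = min(
            range(lo, hi + 1),
            key=lambda m: local_cost(bounds[k - 1], m, bounds[k + 1]),
        )
        refined.append(best)
        bounds[k] = best
    # objective at the refined breakpoints
    edges = [0, *sorted(refined), n]
    sse = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        i, j, w = a, b, b - a
        sse += float((QQ[j] - QQ[i]) - ((S[j] - S[i]) ** 2).sum() / w)
    return sorted(refined), sse + gamma * len(refined) - gamma


def multisample_segment(
    ratios: RatioProfile,
    gamma: float = 20.0,
    dp_max_bins: int = 1000,
) -> tuple[dict, SegmentedProfile]:
    """Shared-breakpoint segmentation of all cells.

    Returns ``(breakpoints, segmented)`` where ``breakpoints`` maps each
    chromosome to the interior breakpoint offsets (in that chromosome's
    usable-bin coordinates) and ``segmented`` holds every cell's
    per-segment means over the shared segments.
    """
    if len(ratios.cell_ids) < 1:
        raise ValueError("need at least one cell")
    usable = ratios.usable
    rows = []
    breakpoints: dict[str, list[int]] = {}
    for chrom, sl in ratios.bins.chrom_slices().items():
        mask = usable[sl.start : sl.stop]
        if not mask.any():
            continue
        gidx = np.arange(sl.start, sl.stop)[mask]
        R = ratios.ratios[gidx, :]
        if np.isnan(R).any():
            raise ValueError(f"NaN ratios in usable bins on {chrom}")
        if R.shape[0] <= dp_max_bins:
            cuts, _ = _joint_dp(R, gamma)
        else:
            cuts, _ = _joint_dp_coarse(R, gamma, dp_max_bins)
        breakpoints[chrom] = cuts
        edges = [0, *cuts, R.shape[0]]
        for a, b in zip(edges[:-1], edges[1:]):
            means = R[a:b].mean(axis=0)
            for ci, cell in enumerate(ratios.cell_ids):
                rows.append(
                    {
                        "cell_id": cell,
                        "chrom": chrom,
                        "start_bin": int(gidx[a]),
                        "end_bin": int(gidx[b - 1]),
                        "n_bins": b - a,
                        "mean_ratio": float(means[ci]),
                    }
                )
    seg = pd.DataFrame(
        rows,
        columns=["cell_id", "chrom", "start_bin", "end_bin", "n_bins", "mean_ratio"],
    )
    return breakpoints, SegmentedProfile(
        segments=seg, bins=ratios.bins, provenance="population"
    )


def filter_short_segments(segments: pd.DataFrame, min_bins: int = 10) -> pd.DataFrame:
    """Drop shared segments spanning fewer than ``min_bins`` usable bins.

    Removed segments are excluded from event calling outright; their
    bins are not re-absorbed into neighbors.
    """
    if len(segments) == 0:
        return segments.copy()
    out = segments[segments["n_bins"] >= min_bins].reset_index(drop=True)
    if len(out) == 0:
        warnings.warn("all segments removed by the short-segment filter", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# trinary state calling


def call_event_state(mean_ratio: float, config: EventCallConfig | None = None):
    """Trinary call for one segment-mean ratio; may return AMBIGUOUS.

    ratio >= 1.4 -> +1, ratio <= 0.6 -> -1, 0.7 < ratio < 1.3 -> 0;
    the closed bands [0.6, 0.7] and [1.3, 1.4] are AMBIGUOUS.
    """
    config = config or EventCallConfig()
    if mean_ratio < 0 or not np.isfinite(mean_ratio):
        raise ValueError(f"invalid mean ratio {mean_ratio!r}")
    if mean_ratio >= config.amp_cutoff:
        return 1
    if mean_ratio <= config.del_cutoff:
        return -1
    if config.neutral_low < mean_ratio < config.neutral_high:
        return 0
    return AMBIGUOUS


def bayesian_resolve(
    mean_ratio: float,
    n_bins: int,
    config: EventCallConfig | None = None,
    priors=None,
    state_sd: float | None = None,
) -> int:
    """Resolve an ambiguous segment mean to its most probable state.

    Posterior(state) ∝ prior(state) * N(mean_ratio; state mean,
    state SD / sqrt(n_bins)).  Exact posterior ties prefer neutral,
    then the state with the larger prior.
    """
    config = config or EventCallConfig()
    if priors is None:
        priors = config.priors or (1 / 3, 1 / 3, 1 / 3)
    priors = np.asarray(priors, float)
    if abs(priors.sum() - 1.0) > 1e-6:
        raise ValueError("priors must sum to 1")
    sd = state_sd if state_sd is not None else (config.state_sd or 0.1)
    se = sd / np.sqrt(max(n_bins, 1))
    means = np.asarray(config.state_means, float)
    with np.errstate(divide="ignore"):
        logpost = np.where(
            priors > 0,
            np.log(priors) - 0.5 * ((mean_ratio - means) / se) ** 2,
            -np.inf,
        )
    states = np.array([-1, 0, 1])
    if not np.isfinite(logpost).any():
        warnings.warn(
            "all posteriors vanished; falling back to neutral", stacklevel=2
        )
        return 0
    best = logpost.max()
    tied = np.isclose(logpost, best, rtol=0, atol=1e-12)
    if tied.sum() > 1:
        if tied[1]:  # neutral among the tied states
            return 0
        cand = np.where(tied)[0]
        return int(states[cand[np.argmax(priors[cand])]])
    return int(states[int(np.argmax(logpost))])


def build_event_matrix(
    states: pd.DataFrame,
    segments: pd.DataFrame,
    cells: pd.DataFrame,
    bins: GenomeBins,
) -> EventMatrix:
    """Assemble the trinary matrix, dropping sex-chromosome segments.

    ``states`` columns: cell_id, segment index (into ``segments``),
    state.  All-zero columns are retained — they still contribute
    branch lengths of zero to the tree.
    """
    keep = segments[~segments["chrom"].isin(bins.sex_chroms)].reset_index()
    keep = keep.sort_values(["index"]).reset_index(drop=True)
    seg_pos = {int(old): new for new, old in enumerate(keep["index"])}
    cell_ids = list(cells["cell_id"])
    cell_pos = {c: i for i, c in enumerate(cell_ids)}
    M = np.full((len(cell_ids), len(keep)), 127, dtype=np.int8)
    for r in states.itertuples():
        j = seg_pos.get(int(r.segment))
        if j is None:
            continue  # sex-chromosome segment: ignored
        M[cell_pos[r.cell_id], j] = int(r.state)
    if (M == 127).any():
        raise ValueError("missing state for some (cell, segment) pair")
    seg_out = keep.drop(columns=["index"]).copy()
    starts = bins.table["start"].to_numpy()
    ends = bins.table["end"].to_numpy()
    seg_out["start_bp"] = starts[seg_out["start_bin"].to_numpy()]
    seg_out["end_bp"] = ends[seg_out["end_bin"].to_numpy()]
    return EventMatrix(states=M, segments=seg_out, cells=cells.copy())


def call_events(
    ratios: RatioProfile,
    config: EventCallConfig | None = None,
) -> tuple[EventMatrix, pd.DataFrame]:
    """Full event-calling path: joint segmentation to trinary matrix.

    Runs the shared-breakpoint segmentation, removes short segments,
    classifies every (cell, segment) mean, estimates the Bayes model
    (neutral-segment SD; add-one-smoothed empirical state priors) from
    the unambiguous calls, resolves the ambiguous ones, and assembles
    the autosome-only event matrix.  Also returns the resolution log
    (one row per ambiguous call).
    """
    config = config or EventCallConfig()
    config.validate()
    _, segprof = multisample_segment(
        ratios, gamma=config.gamma, dp_max_bins=config.dp_max_bins
    )
    shared = (
        segprof.segments[["chrom", "start_bin", "end_bin", "n_bins"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )
    shared = filter_short_segments(shared, config.min_bins)

    usable = ratios.usable
    state_rows = []
    ambiguous = []  # (cell_id, seg_idx, ratio, n_bins)
    neutral_bins: list[np.ndarray] = []
    counts = np.zeros(3)  # unambiguous tallies: del, neutral, amp
    for si, segrow in enumerate(shared.itertuples()):
        gidx = np.arange(segrow.start_bin, segrow.end_bin + 1)
        gidx = gidx[usable[gidx]]
        vals = ratios.ratios[gidx, :]
        means = np.nanmean(vals, axis=0)
        for ci, cell in enumerate(ratios.cell_ids):
            st = call_event_state(float(means[ci]), config)
            if st == AMBIGUOUS:
                ambiguous.append((cell, si, float(means[ci]), len(gidx)))
            else:
                state_rows.append(
                    {"cell_id": cell, "segment": si, "state": int(st)}
                )
                counts[int(st) + 1] += 1
                if st == 0:
                    neutral_bins.append(vals[:, ci])
    if config.state_sd is not None:
        sd = config.state_sd
    elif neutral_bins:
        sd = float(np.nanstd(np.concatenate(neutral_bins)))
        sd = max(sd, 1e-6)
    else:
        sd = 0.1
    priors = (
        np.asarray(config.priors, float)
        if config.priors is not None
        else (counts + 1.0) / (counts.sum() + 3.0)
    )
    log_rows = []
    for cell, si, ratio, nb in ambiguous:
        st = bayesian_resolve(ratio, nb, config, priors=priors, state_sd=sd)
        state_rows.append({"cell_id": cell, "segment": si, "state": st})
        log_rows.append(
            {
                "cell_id": cell,
                "segment": si,
                "mean_ratio": ratio,
                "n_bins": nb,
                "resolved_state": st,
            }
        )
    states_df = pd.DataFrame(
        state_rows, columns=["cell_id", "segment", "state"]
    )
    matrix = build_event_matrix(states_df, shared, ratios.cells, ratios.bins)
    log = pd.DataFrame(
        log_rows,
        columns=["cell_id", "segment", "mean_ratio", "n_bins", "resolved_state"],
    )
    return matrix, log
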