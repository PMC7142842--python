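"""Synthetic single-cell low-pass WGS data with known clonal ground truth.

The generator emulates the data a MALBAC-amplified, ~0.3x-depth
single-cell CNV experiment produces after binning: clonal populations of
tumor cells sharing copy-number events laid down on a clone tree, normal
diploid outgroup cells ("blood"), a smooth GC-dependent coverage bias,
and overdispersed per-bin counts.  Every downstream stage (GC
normalization, segmentation, event calling, tree building) is testable
against the returned :class:`ClonalTruth`.

Copy-number events are contiguous bin intervals with integer copy change
in {-2, -1, +1, +2} on a diploid baseline, floored at copy 0.  The two
placement modes mirror the two modes of CNA accumulation seen in tumors:
``punctuated`` concentrates events on the trunk branch (an early burst
shared by all tumor cells) while ``gradual`` spreads them evenly over
all branches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeBins

__all__ = [
    "SimulationConfig",
    "ClonalTruth",
    "generate_genome_bins",
    "simulate_clonal_truth",
    "simulate_cell_counts",
    "gc_bias_curve",
    "write_simulation",
    "write_synthetic_sam",
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic experiment.

    Defaults describe a scaled-down mouse-like genome (11 autosomes plus
    one sex chromosome, 150 bins of 500 kb each) carrying 4 tumor clones
    of 10 cells plus 4 normal blood cells; events are kept at least
    ``event_guard_bins`` apart so neutral stretches separate them, as in
    real tumor genomes where CNAs cover a minority of the genome.  ``mean_reads_per_bin=200``
    with ``overdispersion=0.005`` gives a per-bin copy-ratio coefficient
    of variation of ~0.1 at diploid coverage, the noise regime the
    pipeline's defaults are tuned for.
    """

    n_chromosomes: int = 12
    bins_per_chromosome: int = 150
    bin_size: int = 500_000
    include_sex_chromosome: bool = True
    n_clones: int = 4
    n_cells_per_clone: int = 10
    n_normal_cells: int = 4
    events_per_branch: int = 3
    mode: str = "punctuated"  # or "gradual"
    trunk_fraction: float = 0.5
    mean_reads_per_bin: float = 200.0
    gc_bias_coefficients: tuple = (1.0, -2.0)  # linear, quadratic around GC 0.45
    overdispersion: float = 0.005
    nongreen_fraction: float = 0.3
    event_min_bins: int = 20
    event_max_bins: int = 30
    event_deltas: tuple = (-1, 1, 2)
    event_guard_bins: int = 20
    allow_sex_events: bool = False
    gc_center: float = 0.45
    gc_sd: float = 0.06
    gc_ar_rho: float = 0.9
    gc_range: tuple = (0.30, 0.62)
    mouse_id: str = "M1"
    seed: int = 0

    def validate(self) -> None:
        if self.n_chromosomes <= 0 or self.bins_per_chromosome <= 0:
            raise ValueError("genome dimensions must be positive")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.n_clones <= 0 or self.n_cells_per_clone <= 0:
            raise ValueError("clone counts must be positive")
        if self.n_clones > self.n_clones * self.n_cells_per_clone:
            raise ValueError("more clones than cells")
        if self.n_normal_cells < 0:
            raise ValueError("n_normal_cells must be >= 0")
        if self.mode not in ("punctuated", "gradual"):
            raise ValueError("mode must be 'punctuated' or 'gradual'")
        if self.mean_reads_per_bin < 0:
            raise ValueError("mean_reads_per_bin must be >= 0")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")
        if self.events_per_branch < 0:
            raise ValueError("events_per_branch must be >= 0")
        if not 0 < self.event_min_bins <= self.event_max_bins:
            raise ValueError("invalid event span bounds")
        if not 0.0 <= self.trunk_fraction <= 1.0:
            raise ValueError("trunk_fraction must be in [0, 1]")
        if not all(d in (-2, -1, 1, 2) for d in self.event_deltas):
            raise ValueError("event deltas restricted to {-2,-1,+1,+2}")


@dataclass
class ClonalTruth:
    """Ground truth of one simulated tumor.

    ``parent`` maps every tree node to its parent; the root is
    ``"diploid"`` and tumor clones are leaves named ``cloneK``.  The
    branch into a node is identified by the node's name.  ``profiles``
    holds the integer copy number of every clone (rows) over all bins,
    and ``"normal"`` indexes the all-2 outgroup profile.
    """

    parent: dict
    profiles: pd.DataFrame  # index: clone names + "normal"; columns: bin idx
    cells: pd.DataFrame  # cell_id, clone, label, mouse
    events: pd.DataFrame  # chrom, start_bin, end_bin, delta, branch

    @property
    def clones(self) -> list[str]:
        return [c for c in self.profiles.index if c != "normal"]

    def root_path(self, node: str) -> list[str]:
        """Branches (node names) on the path from the root down to node."""
        path = []
        while node != "diploid":
            path.append(node)
            node = self.parent[node]
        return path[::-1]

    def event_state_matrix(self) -> np.ndarray:
        """Expected trinary state of every cell (rows) for every event (cols)."""
        n_cells = len(self.cells)
        out = np.zeros((n_cells, len(self.events)), dtype=np.int8)
        carrier_cache = {}
        for j, ev in enumerate(self.events.itertuples()):
            if ev.branch not in carrier_cache:
                carriers = {
                    c
                    for c in self.clones
                    if ev.branch in self.root_path(c)
                }
                carrier_cache[ev.branch] = carriers
            sign = 1 if ev.delta > 0 else -1
            mask = self.cells["clone"].isin(carrier_cache[ev.branch]).to_numpy()
            out[mask, j] = sign
        return out

    def clone_tree_newick(self) -> str:
        """Rooted newick of the clone tree with the diploid outgroup leaf."""
        children: dict[str, list[str]] = {}
        for child, par in self.parent.items():
            children.setdefault(par, []).append(child)

        def render(node: str) -> str:
            kids = children.get(node, [])
            if not kids:
                return node
            return "(" + ",".join(render(k) for k in sorted(kids)) + ")" + node

        # root "diploid" is both the outgroup taxon and the tree root
        top = children["diploid"]
        inner = ",".join(render(k) for k in sorted(top))
        return f"(diploid_leaf,{inner})diploid;"


def gc_bias_curve(gc: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Quadratic GC bias, normalized to unit mean over the given bins."""
    a, b = config.gc_bias_coefficients
    x = np.asarray(gc, float) - config.gc_center
    g = 1.0 + a * x + b * x**2
    g = np.clip(g, 0.05, None)
    return g / g.mean()


def generate_genome_bins(config: SimulationConfig) -> GenomeBins:
    """Build the binned genome: fixed-width bins with autocorrelated GC.

    GC content follows a stationary AR(1) process along each chromosome,
    scaled to ``gc_sd`` around ``gc_center`` and clipped to ``gc_range``
    — smooth enough for LOESS to be a sensible corrector, variable
    enough for the bias to matter.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows = []
    for c in range(config.n_chromosomes):
        sex = config.include_sex_chromosome and c == config.n_chromosomes - 1
        chrom = "chrX" if sex else f"chr{c + 1}"
        n = config.bins_per_chromosome
        z = np.empty(n)
        z[0] = rng.normal()
        innov = rng.normal(size=n - 1) if n > 1 else np.empty(0)
        rho = config.gc_ar_rho
        for j in range(1, n):
            z[j] = rho * z[j - 1] + np.sqrt(1 - rho**2) * innov[j - 1]
        gc = np.clip(config.gc_center + config.gc_sd * z, *config.gc_range)
        starts = np.arange(n, dtype=np.int64) * config.bin_size
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + config.bin_size,
                    "gc": gc,
                    "usable": True,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    sex_chroms = frozenset({"chrX"}) if config.include_sex_chromosome else frozenset()
    return GenomeBins(table, sex_chroms=sex_chroms, bin_size=config.bin_size)


def _build_clone_tree(n_clones: int, rng: np.random.Generator) -> dict:
    """Random rooted binary tree over clones below a single trunk branch.

    Returns the parent map: root "diploid" -> "trunk" -> binary subtree
    with leaves clone1..cloneK.  With one clone the trunk leads straight
    to it.
    """
    parent = {}
    leaves = [f"clone{i + 1}" for i in range(n_clones)]
    if n_clones == 1:
        parent["clone1"] = "diploid"
        return parent
    nodes = list(leaves)
    k = 0
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        k += 1
        anc = f"node{k}"
        parent[nodes[i]] = anc
        parent[nodes[j]] = anc
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)] + [anc]
    trunk = "trunk"
    for n in nodes:
        parent[n] = trunk
    parent[trunk] = "diploid"
    return parent


def _branch_event_counts(
    branches: list[str], config: SimulationConfig
) -> dict[str, int]:
    """Distribute the total event budget over branches by evolution mode."""
    total = config.events_per_branch * len(branches)
    counts = dict.fromkeys(branches, 0)
    if total == 0:
        return counts
    nontrunk = [b for b in branches if b != "trunk"]
    if config.mode == "punctuated" and "trunk" in counts and nontrunk:
        trunk_n = int(np.ceil(config.trunk_fraction * total))
        trunk_n = min(max(trunk_n, 1), max(total - len(nontrunk), 1))
        counts["trunk"] = trunk_n
        rest = total - trunk_n
        for i in range(rest):
            counts[nontrunk[i % len(nontrunk)]] += 1
    else:
        for i in range(total):
            counts[branches[i % len(branches)]] += 1
    return counts


def simulate_clonal_truth(
    bins: GenomeBins, config: SimulationConfig
) -> ClonalTruth:
    """Lay a clone tree and non-overlapping CNA events onto the genome.

    Events are contiguous bin intervals (span uniform in
    ``[event_min_bins, event_max_bins]``) placed without overlap and
    separated by at least ``event_guard_bins`` neutral bins; by default
    only autosomes are used, so sex-chromosome exclusion downstream can
    be tested by setting ``allow_sex_events``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    parent = _build_clone_tree(config.n_clones, rng)
    branches = [n for n in parent if parent[n] != n]
    # stable genome-independent order: trunk first, then sorted
    branches = sorted(branches, key=lambda b: (b != "trunk", b))
    counts = _branch_event_counts(branches, config)

    # free runs of placeable bins (global indices, half-open), given the
    # already-placed events inflated by the guard separation
    chrom_slices = bins.chrom_slices()
    chrom_ranges = [
        (sl.start, sl.stop)
        for chrom, sl in chrom_slices.items()
        if config.allow_sex_events or not bins.is_sex(chrom)
    ]
    placed_intervals: list[tuple[int, int]] = []  # half-open, per placement

    def free_runs(guard: int) -> list[tuple[int, int]]:
        out = []
        for lo, hi in chrom_ranges:
            cuts = sorted(
                (max(lo, s - guard), min(hi, e + guard))
                for s, e in placed_intervals
                if s < hi and e > lo
            )
            cur = lo
            for s, e in cuts:
                if s > cur:
                    out.append((cur, s))
                cur = max(cur, e)
            if cur < hi:
                out.append((cur, hi))
        return out

    events = []
    for branch in branches:
        for _ in range(counts[branch]):
            span = int(rng.integers(config.event_min_bins, config.event_max_bins + 1))
            placed = False
            guard = config.event_guard_bins
            while not placed:
                runs = free_runs(guard)
                for length in range(span, config.event_min_bins - 1, -1):
                    slots = [max(0, (hi - lo) - length + 1) for lo, hi in runs]
                    total_slots = int(np.sum(slots))
                    if total_slots == 0:
                        continue
                    pick = int(rng.integers(total_slots))
                    for ri, ns in enumerate(slots):
                        if pick < ns:
                            lo, hi = runs[ri]
                            start = lo + pick
                            end = start + length  # half-open
                            delta = int(rng.choice(config.event_deltas))
                            chrom = bins.table["chrom"].iloc[start]
                            events.append(
                                {
                                    "chrom": chrom,
                                    "start_bin": start,
                                    "end_bin": end - 1,
                                    "delta": delta,
                                    "branch": branch,
                                }
                            )
                            placed_intervals.append((start, end))
                            placed = True
                            break
                        pick -= ns
                    if placed:
                        break
                if placed:
                    break
                if guard == 0:
                    raise ValueError(
                        "genome too small to place all requested events "
                        "without overlap"
                    )
                # tight genome: relax the separation and retry
                guard //= 2
    events_df = pd.DataFrame(
        events, columns=["chrom", "start_bin", "end_bin", "delta", "branch"]
    )

    # clone copy-number profiles: 2 + cumulative root-path deltas, floor 0
    truth = ClonalTruth(
        parent=parent,
        profiles=pd.DataFrame(),
        cells=pd.DataFrame(),
        events=events_df,
    )
    prof = {}
    for clone in [f"clone{i + 1}" for i in range(config.n_clones)]:
        p = np.full(bins.n_bins, 2, dtype=np.int64)
        path = set(truth.root_path(clone))
        for ev in events_df.itertuples():
            if ev.branch in path:
                p[ev.start_bin : ev.end_bin + 1] += ev.delta
        prof[clone] = np.maximum(p, 0)
    prof["normal"] = np.full(bins.n_bins, 2, dtype=np.int64)
    truth.profiles = pd.DataFrame(prof).T

    # cells: tumor cells round-robin over clones, plus normal blood cells
    cell_rows = []
    for i in range(config.n_clones):
        clone = f"clone{i + 1}"
        for j in range(config.n_cells_per_clone):
            label = "non-green" if rng.random() < config.nongreen_fraction else "green"
            cell_rows.append(
                {
                    "cell_id": f"{config.mouse_id}_{clone}_c{j + 1}",
                    "clone": clone,
                    "label": label,
                    "mouse": config.mouse_id,
                }
            )
    for j in range(config.n_normal_cells):
        cell_rows.append(
            {
                "cell_id": f"{config.mouse_id}_blood_c{j + 1}",
                "clone": "normal",
                "label": "blood",
                "mouse": config.mouse_id,
            }
        )
    truth.cells = pd.DataFrame(cell_rows)
    return truth


def simulate_cell_counts(
    truth: ClonalTruth, bins: GenomeBins, config: SimulationConfig
):
    """Draw per-cell binned read counts.

    Expected count in bin j of cell i is
    ``mean_reads_per_bin * (cn_ij / 2) * g(gc_j)`` with g the quadratic
    GC bias normalized to unit mean.  Counts are gamma-Poisson
    (negative-binomial-like) with variance ``mu + overdispersion*mu^2``;
    ``overdispersion=0`` is exactly Poisson.
    """
    from .bincounts import BinCountMatrix  # local import to avoid a cycle

    config.validate()
    rng = np.random.default_rng(config.seed + 2)
    g = gc_bias_curve(bins.gc, config)
    cn = truth.profiles.loc[truth.cells["clone"].to_numpy()].to_numpy().T
    lam = config.mean_reads_per_bin * (cn / 2.0) * g[:, None]
    if config.overdispersion > 0:
        shape = 1.0 / config.overdispersion
        mix = rng.gamma(shape, 1.0 / shape, size=lam.shape)
        lam = lam * mix
    counts = rng.poisson(lam).astype(np.int64)
    return BinCountMatrix(bins=bins, counts=counts, cells=truth.cells.copy())


# ---------------------------------------------------------------------------
# writers


def write_simulation(outdir, bins: GenomeBins, truth: ClonalTruth, counts) -> dict:
    """Write bins (BED), counts (TSV), truth (newick + TSV) and metadata.

    Returns the mapping of artifact name to path.
    """
    import json
    from pathlib import Path

    from . import io as cio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "bins_bed": outdir / "bins.bed",
        "counts_tsv": outdir / "counts.tsv",
        "cells_tsv": outdir / "cells.tsv",
        "truth_json": outdir / "truth.json",
        "events_tsv": outdir / "truth_events.tsv",
    }
    bins.to_bed(paths["bins_bed"])
    cio.write_counts_tsv(paths["counts_tsv"], counts)
    truth.cells.to_csv(paths["cells_tsv"], sep="\t", index=False)
    truth.events.to_csv(paths["events_tsv"], sep="\t", index=False)
    with open(paths["truth_json"], "w") as fh:
        json.dump(
            {
                "clone_tree_newick": truth.clone_tree_newick(),
                "parent": truth.parent,
                "events_tsv": paths["events_tsv"].name,
            },
            fh,
            indent=2,
        )
    return {k: str(v) for k, v in paths.items()}


def write_synthetic_sam(path, bins: GenomeBins, reads: pd.DataFrame) -> None:
    """Write a minimal single-cell SAM fixture for bin-counting tests.

    ``reads`` columns: chrom, pos (0-based leftmost), mapq, and optional
    duplicate / unmapped boolean flags and span (bp, default 100).
    """
    chrom_len = {}
    for chrom, sub in bins.table.groupby("chrom", sort=False):
        chrom_len[chrom] = int(sub["end"].max())
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for chrom in bins.chroms:
            fh.write(f"@SQ\tSN:{chrom}\tLN:{chrom_len[chrom]}\n")
        for i, r in enumerate(reads.itertuples()):
            dup = bool(getattr(r, "duplicate", False))
            unmapped = bool(getattr(r, "unmapped", False))
            span = int(getattr(r, "span", 100))
            flag = (1024 if dup else 0) | (4 if unmapped else 0)
            if unmapped:
                fh.write(f"r{i}\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n")
                continue
            fh.write(
                f"r{i}\t{flag}\t{r.chrom}\t{int(r.pos) + 1}\t{int(r.mapq)}\t"
                f"{span}M\t*\t0\t0\t*\t*\n"
            )
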