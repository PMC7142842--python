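"""End-to-end pipeline: simulate/ingest -> ratios -> segments -> events -> tree.

Stages communicate through files in the run directory, so any stage can
be re-run or resumed from its predecessors' outputs.  A manifest
records the 8 stage outputs (simulate, count, normalize, segment,
jointseg, events, tree, report), the effective configuration, input
hashes and the package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .bincounts import count_reads_in_bins, filter_aberrant_bins, gc_normalize
from .cohort import cna_burden_summary
from .genome import GenomeBins
from .phylogeny import assess_clonal_origin, parsimony_ratchet, root_and_acctran
from .popseg import EventCallConfig, call_events
from .segmentation import CbsParams, cbs_segment, merge_levels
from .simulate import (
    SimulationConfig,
    generate_genome_bins,
    simulate_cell_counts,
    simulate_clonal_truth,
    write_simulation,
)

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = [
    "simulate",
    "count",
    "normalize",
    "segment",
    "jointseg",
    "events",
    "tree",
    "report",
]


@dataclass
class PipelineConfig:
    """Every stage parameter, with the published pipeline defaults.

    Input is either the synthetic generator (``simulate=True``) or a
    counts TSV + bins BED (+ optional cell metadata TSV), or per-cell
    SAM/BAM files counted against the bins.
    """

    simulate: bool = True
    counts_tsv: str | None = None
    bins_bed: str | None = None
    cells_tsv: str | None = None
    alignments: list = field(default_factory=list)
    bin_size: int = 500_000
    min_mapping_quality: int = 40
    drop_duplicates: bool = True
    mad_multiplier: float = 5.0
    loess_span: float = 0.3
    ratchet_iterations: int = 200
    reweight_fraction: float = 0.25
    merge_p_threshold: float = 1e-4
    seed: int = 0
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    cbs: CbsParams = field(default_factory=CbsParams)
    events: EventCallConfig = field(default_factory=EventCallConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sub = {}
        for key, typ in (("sim", SimulationConfig), ("cbs", CbsParams), ("events", EventCallConfig)):
            if key in d:
                section = d.pop(key) or {}
                known = {f.name for f in dataclasses.fields(typ)}
                unknown = set(section) - known
                if unknown:
                    raise ValueError(f"unknown {key} config keys: {sorted(unknown)}")
                sub[key] = typ(**section)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d, **sub)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def propagate_seed(self) -> None:
        """Push the pipeline seed into stage configs that use randomness."""
        self.sim.seed = self.seed
        self.cbs.seed = self.seed


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _outgroup_cells(cells: pd.DataFrame, matrix) -> list[str]:
    blood = list(cells.loc[cells["label"].isin(["blood", "normal"]), "cell_id"])
    if blood:
        return blood
    zero = [
        c
        for c, row in zip(matrix.cell_ids, matrix.states)
        if not np.any(row != 0)
    ]
    if zero:
        logger.warning("no blood cells; rooting on zero-event cells instead")
        return zero
    logger.warning("no diploid cells at all; rooting on the first cell")
    return [matrix.cell_ids[0]]


def run_pipeline(config: PipelineConfig, outdir, resume: bool = False) -> dict:
    """Execute all stages into ``outdir``; returns the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.propagate_seed()
    manifest: dict = {
        "config": config.to_dict(),
        "stages": {},
        "inputs": {},
    }
    try:
        from importlib.metadata import version

        manifest["version"] = version("cnatree")
    except Exception:  # pragma: no cover
        manifest["version"] = "unknown"

    def done(stage, paths):
        manifest["stages"][stage] = [str(p) for p in paths]
        cio.write_json(out / "manifest.json", manifest)

    def fresh(paths) -> bool:
        return resume and all(Path(p).exists() for p in paths)

    # -- stage 1: simulate (or register external inputs) -------------------
    stage = "simulate"
    try:
        if config.simulate:
            sim_paths = [
                out / "bins.bed",
                out / "counts.tsv",
                out / "cells.tsv",
                out / "truth.json",
                out / "truth_events.tsv",
            ]
            if not fresh(sim_paths):
                bins = generate_genome_bins(config.sim)
                truth = simulate_clonal_truth(bins, config.sim)
                counts = simulate_cell_counts(truth, bins, config.sim)
                write_simulation(out, bins, truth, counts)
            done(stage, sim_paths)
            bins_bed, counts_tsv, cells_tsv = sim_paths[0], sim_paths[1], sim_paths[2]
        else:
            if config.bins_bed is None:
                raise FileNotFoundError("bins_bed is required when simulate=False")
            for p in filter(None, [config.bins_bed, config.counts_tsv, config.cells_tsv]):
                if not Path(p).exists():
                    raise FileNotFoundError(f"input not found: {p}")
                manifest["inputs"][str(p)] = _sha256(p)
            bins_bed = Path(config.bins_bed)
            counts_tsv = Path(config.counts_tsv) if config.counts_tsv else None
            cells_tsv = Path(config.cells_tsv) if config.cells_tsv else None
            done(stage, [p for p in (bins_bed, counts_tsv, cells_tsv) if p])
    except Exception as e:
        raise RuntimeError(f"stage '{stage}' failed: {e}") from e

    # -- stage 2: count -----------------------------------------------------
    stage = "count"
    try:
        bins = GenomeBins.from_bed(bins_bed, bin_size=config.bin_size)
        cells = (
            pd.read_csv(cells_tsv, sep="\t", dtype=str)
            if cells_tsv and Path(cells_tsv).exists()
            else None
        )
        counts_out = out / "counts.tsv"
        if config.alignments:
            counts = count_reads_in_bins(
                config.alignments,
                bins,
                min_mapping_quality=config.min_mapping_quality,
                drop_duplicates=config.drop_duplicates,
                cells=cells,
            )
            cio.write_counts_tsv(counts_out, counts)
        else:
            if counts_tsv is None:
                raise FileNotFoundError("no counts_tsv and no alignments given")
            counts = cio.read_counts_tsv(counts_tsv, bins, cells)
            if Path(counts_tsv).resolve() != counts_out.resolve():
                cio.write_counts_tsv(counts_out, counts)
        done(stage, [counts_out])
    except Exception as e:
        raise RuntimeError(f"stage '{stage}' failed: {e}") from e

    # -- stage 3: normalize (aberrant-bin filter + GC LOESS) ----------------
    stage = "normalize"
    try:
        ref = list(counts.cells.loc[counts.cells["label"].isin(["blood", "normal"]), "cell_id"])
        bins_f = filter_aberrant_bins(
            counts, reference_cells=ref or None, mad_multiplier=config.mad_multiplier
        )
        counts.bins = bins_f
        profile = gc_normalize(counts, bins_f, loess_span=config.loess_span)
        paths = [
            out / "ratios.tsv",
            out / "ratios_log2.tsv",
            out / "usable_bins.bed",
            out / "qc.tsv",
        ]
        cio.write_ratio_tsv(paths[0], profile)
        cio.write_ratio_tsv(paths[1], profile, log2=True)
        bins_f.to_bed(paths[2])
        cio.write_qc_report(paths[3], counts, profile)
        done(stage, paths)
    except Exception as e:
        raise RuntimeError(f"stage '{stage}' failed: {e}") from e

    # -- stage 4: per-cell CBS + MergeLevels --------------------------------
    stage = "segment"
    try:
        seg = cbs_segment(profile, config.cbs)
        seg = merge_levels(seg, profile, config.merge_p_threshold)
        seg_path = out / "segments_cbs.seg"
        cio.write_seg(seg_path, seg)
        done(stage, [seg_path])
    except Exception as e:
        raise RuntimeError(f"stage '{stage}' failed: {e}") from e

    # -- stage 5+6: joint segmentation and event calling --------------------
    stage = "jointseg"
    try:
        from .popseg import multisample_segment

        _, popseg_prof = multisample_segment(
            profile, gamma=config.events.gamma, dp_max_bins=config.events.dp_max_bins
        )
        pop_path = out / "segments_population.seg"
        cio.write_seg(pop_path, popseg_prof)
        done(stage, [pop_path])
    except Exception as e:
        raise RuntimeError(f"stage '{stage}' failed: {e}") from e

    stage = "events"
    try:
        matrix, res_log = call_events(profile, config.events)
        ev_path = out / "event_matrix.tsv"
        log_path = out / "resolution_log.tsv"
        cio.write_event_matrix_tsv(ev_path, matrix)
        res_log.to_csv(log_path, sep="\t", index=False)
        done(stage, [ev_path, log_path])
    except Exception as e:
        raise RuntimeError(f"stage '{stage}' failed: {e}") from e

    # -- stage 7: tree ------------------------------------------------------
    stage = "tree"
    try:
        keep = ~matrix.cells["label"].isin(["bulk"])
        from .popseg import EventMatrix

        tree_matrix = EventMatrix(
            states=matrix.states[keep.to_numpy()],
            segments=matrix.segments,
            cells=matrix.cells[keep].reset_index(drop=True),
        )
        trees, score = parsimony_ratchet(
            tree_matrix,
            n_iterations=config.ratchet_iterations,
            reweight_fraction=config.reweight_fraction,
            seed=config.seed,
        )
        outgroup = _outgroup_cells(tree_matrix.cells, tree_matrix)
        cna_tree = root_and_acctran(trees[0], tree_matrix, outgroup)
        paths = [out / "tree.nwk", out / "branch_events.tsv", out / "tree_search.json"]
        with open(paths[0], "w") as fh:
            fh.write(cna_tree.newick() + "\n")
        cna_tree.branch_events_table().to_csv(paths[1], sep="\t", index=False)
        cio.write_json(
            paths[2],
            {
                "parsimony_score": score,
                "n_best_topologies": len(trees),
                "best_newicks": [t.to_newick() for t in trees],
            },
        )
        done(stage, paths)
    except Exception as e:
        raise RuntimeError(f"stage '{stage}' failed: {e}") from e

    # -- stage 8: report ----------------------------------------------------
    stage = "report"
    try:
        origin = assess_clonal_origin(cna_tree, tree_matrix)
        burden = cna_burden_summary({"sample": (cna_tree, tree_matrix)})
        paths = [out / "origin_report.json", out / "burden_summary.json"]
        cio.write_json(paths[0], origin)
        cio.write_json(paths[1], burden.to_dict(orient="records"))
        txt = out / "origin_report.txt"
        with open(txt, "w") as fh:
            fh.write(_origin_text(origin))
        done(stage, paths + [txt])
    except Exception as e:
        raise RuntimeError(f"stage '{stage}' failed: {e}") from e

    return manifest


def _origin_text(origin: dict) -> str:
    if origin.get("status") != "ok":
        return origin.get("status", "unknown") + "\n"
    lines = [f"inferred independent tumor origins: {origin['n_origins']}"]
    lc = origin.get("largest_clade")
    if lc:
        lines.append(
            f"largest clonal clade: {lc['n_cells']} cells, "
            f"{lc['stem_events']} stem events"
        )
        for lab, n in sorted(lc["label_counts"].items()):
            lines.append(f"  {lab}: {n} ({lc['label_fractions'][lab]:.1%})")
        lines.append(f"label mixing (internal branches): {lc['label_mixing']:.2f}")
    return "\n".join(lines) + "\n"
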