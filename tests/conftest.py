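import numpy as np
import pandas as pd
import pytest

import cnatree as ct


@pytest.fixture(scope="session")
def small_cfg():
    """A compact simulated tumor: fast, but with full structure."""
    return ct.SimulationConfig(
        n_chromosomes=5,
        bins_per_chromosome=120,
        n_clones=3,
        n_cells_per_clone=6,
        n_normal_cells=3,
        events_per_branch=2,
        event_min_bins=20,
        event_max_bins=25,
        event_guard_bins=15,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    bins = ct.generate_genome_bins(small_cfg)
    truth = ct.simulate_clonal_truth(bins, small_cfg)
    counts = ct.simulate_cell_counts(truth, bins, small_cfg)
    return bins, truth, counts


@pytest.fixture(scope="session")
def small_profile(small_sim):
    bins, truth, counts = small_sim
    ref = list(truth.cells.loc[truth.cells["label"] == "blood", "cell_id"])
    bins_f = ct.filter_aberrant_bins(counts, ref)
    counts.bins = bins_f
    return truth, ct.gc_normalize(counts, bins_f)


def make_bins(values_per_chrom, bin_size=500_000, gc=0.45, sex_chroms=()):
    """Quick GenomeBins over chromosomes with the given bin counts."""
    rows = []
    for chrom, n in values_per_chrom.items():
        starts = np.arange(n) * bin_size
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + bin_size,
                    "gc": gc if np.isscalar(gc) else gc[chrom],
                    "usable": True,
                }
            )
        )
    return ct.GenomeBins(
        pd.concat(rows, ignore_index=True),
        sex_chroms=frozenset(sex_chroms),
        bin_size=bin_size,
    )


def make_profile(bins, ratio_matrix, labels=None):
    """RatioProfile around an explicit ratio matrix."""
    n_cells = ratio_matrix.shape[1]
    cells = pd.DataFrame(
        {
            "cell_id": [f"cell{i}" for i in range(n_cells)],
            "label": labels if labels is not None else ["green"] * n_cells,
            "mouse": "M1",
        }
    )
    return ct.RatioProfile(bins=bins, ratios=ratio_matrix, cells=cells)
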