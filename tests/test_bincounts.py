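"""Read counting, aberrant-bin filtering and GC normalization."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cnatree as ct
from cnatree.simulate import gc_bias_curve, write_synthetic_sam

from conftest import make_bins, make_profile


@pytest.fixture()
def two_chrom_bins():
    return make_bins({"chr1": 4, "chr2": 4})


class TestReadCounting:
    def test_mapping_quality_threshold(self, two_chrom_bins, tmp_path):
        reads = pd.DataFrame(
            {"chrom": ["chr1"] * 3, "pos": [100, 200, 300], "mapq": [39, 40, 60]}
        )
        sam = tmp_path / "cell.sam"
        write_synthetic_sam(sam, two_chrom_bins, reads)
        counts = ct.count_reads_in_bins(sam, two_chrom_bins, min_mapping_quality=40)
        assert counts.counts[0, 0] == 2
        assert counts.counts.sum() == 2

    def test_duplicate_flag_dropped(self, two_chrom_bins, tmp_path):
        reads = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "pos": [100, 100],
                "mapq": [60, 60],
                "duplicate": [False, True],
            }
        )
        sam = tmp_path / "cell.sam"
        write_synthetic_sam(sam, two_chrom_bins, reads)
        assert ct.count_reads_in_bins(sam, two_chrom_bins).counts.sum() == 1
        kept = ct.count_reads_in_bins(sam, two_chrom_bins, drop_duplicates=False)
        assert kept.counts.sum() == 2

    def test_leftmost_position_assigns_single_bin(self, two_chrom_bins, tmp_path):
        # spans the bin0/bin1 boundary; leftmost position keeps it in bin 0
        reads = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [499_999], "mapq": [60], "span": [150]}
        )
        sam = tmp_path / "cell.sam"
        write_synthetic_sam(sam, two_chrom_bins, reads)
        counts = ct.count_reads_in_bins(sam, two_chrom_bins)
        assert counts.counts[0, 0] == 1
        assert counts.counts.sum() == 1

    def test_unmapped_and_unknown_chromosome_skipped(self, two_chrom_bins, tmp_path):
        bigger = make_bins({"chr1": 4, "chr2": 4, "chr9": 4})
        reads = pd.DataFrame(
            {
                "chrom": ["chr1", "chr9", "chr1"],
                "pos": [0, 0, 10],
                "mapq": [60, 60, 60],
                "unmapped": [False, False, True],
            }
        )
        sam = tmp_path / "cell.sam"
        write_synthetic_sam(sam, bigger, reads)
        counts = ct.count_reads_in_bins(sam, two_chrom_bins)
        assert counts.counts.sum() == 1


class TestAberrantBinFilter:
    def test_zero_coverage_bin_masked(self):
        bins = make_bins({"chr1": 50})
        counts = np.full((50, 3), 100)
        counts[7, :] = 0
        bcm = ct.BinCountMatrix(
            bins=bins,
            counts=counts,
            cells=pd.DataFrame(
                {"cell_id": ["a", "b", "c"], "label": "blood", "mouse": "M1"}
            ),
        )
        out = ct.filter_aberrant_bins(bcm, ["a", "b", "c"])
        assert not out.usable[7]
        assert out.usable.sum() == 49

    def test_inflated_bin_masked_by_mad_rule(self):
        rng = np.random.default_rng(0)
        bins = make_bins({"chr1": 200})
        counts = rng.poisson(100, size=(200, 4))
        counts[33, :] *= 10
        bcm = ct.BinCountMatrix(
            bins=bins,
            counts=counts,
            cells=pd.DataFrame(
                {"cell_id": list("abcd"), "label": "blood", "mouse": "M1"}
            ),
        )
        out = ct.filter_aberrant_bins(bcm, list("abcd"), mad_multiplier=5.0)
        assert not out.usable[33]
        assert out.usable.sum() == 199

    def test_uniform_counts_nothing_masked(self):
        bins = make_bins({"chr1": 30})
        bcm = ct.BinCountMatrix(
            bins=bins,
            counts=np.full((30, 2), 50),
            cells=pd.DataFrame(
                {"cell_id": ["a", "b"], "label": "blood", "mouse": "M1"}
            ),
        )
        out = ct.filter_aberrant_bins(bcm, ["a", "b"])
        assert out.usable.all()

    def test_all_bins_filtered_is_an_error(self):
        bins = make_bins({"chr1": 5})
        bcm = ct.BinCountMatrix(
            bins=bins,
            counts=np.zeros((5, 2), dtype=int),
            cells=pd.DataFrame(
                {"cell_id": ["a", "b"], "label": "blood", "mouse": "M1"}
            ),
        )
        with pytest.raises(ValueError, match="no usable bins"):
            ct.filter_aberrant_bins(bcm, ["a", "b"])


class TestGcNormalize:
    def _counts_from_bias(self, cfg, bins, scale=100.0):
        g = gc_bias_curve(bins.gc, cfg)
        return np.round(scale * g).astype(np.int64)

    def test_loess_recovers_smooth_bias(self):
        cfg = ct.SimulationConfig(seed=1)
        bins = ct.generate_genome_bins(cfg)
        y = self._counts_from_bias(cfg, bins, scale=1000.0)
        bcm = ct.BinCountMatrix(
            bins=bins,
            counts=y[:, None],
            cells=pd.DataFrame({"cell_id": ["a"], "label": "blood", "mouse": "M1"}),
        )
        prof = ct.gc_normalize(bcm)
        r = prof.ratios[bins.usable, 0]
        assert np.all((r > 0.95) & (r < 1.05))

    def test_residual_gc_correlation_small(self):
        cfg = ct.SimulationConfig(
            n_clones=1, n_cells_per_clone=4, events_per_branch=0, seed=5
        )
        bins = ct.generate_genome_bins(cfg)
        truth = ct.simulate_clonal_truth(bins, cfg)
        counts = ct.simulate_cell_counts(truth, bins, cfg)
        prof = ct.gc_normalize(counts)
        mask = bins.usable & bins.autosomal
        for i in range(4):
            r, _ = stats.pearsonr(prof.ratios[mask, i], bins.gc[mask])
            assert abs(r) < 0.05

    def test_degenerate_gc_constant_counts(self):
        bins = make_bins({"chr1": 120}, gc=0.5)
        bcm = ct.BinCountMatrix(
            bins=bins,
            counts=np.full((120, 1), 77),
            cells=pd.DataFrame({"cell_id": ["a"], "label": "green", "mouse": "M1"}),
        )
        with pytest.warns(UserWarning, match="degenerate GC"):
            prof = ct.gc_normalize(bcm)
        assert np.allclose(prof.ratios[:, 0], 1.0)

    def test_scale_invariance(self):
        cfg = ct.SimulationConfig(seed=7)
        bins = ct.generate_genome_bins(cfg)
        truth = ct.simulate_clonal_truth(bins, cfg)
        counts = ct.simulate_cell_counts(truth, bins, cfg)
        one = ct.BinCountMatrix(
            bins=bins,
            counts=counts.counts[:, :1],
            cells=counts.cells.iloc[:1].reset_index(drop=True),
        )
        scaled = ct.BinCountMatrix(
            bins=bins,
            counts=one.counts * 7,
            cells=one.cells,
        )
        a = ct.gc_normalize(one).ratios
        b = ct.gc_normalize(scaled).ratios
        assert np.allclose(a, b, rtol=1e-9, atol=1e-12, equal_nan=True)

    def test_median_autosomal_ratio_is_one(self, small_profile):
        truth, prof = small_profile
        mask = prof.usable & prof.bins.autosomal
        for i in range(len(prof.cell_ids)):
            med = np.nanmedian(prof.ratios[mask, i])
            assert med == pytest.approx(1.0, abs=1e-9)

    def test_masked_bins_have_no_ratio(self):
        bins = make_bins({"chr1": 150}, gc={"chr1": np.linspace(0.35, 0.55, 150)})
        usable = np.ones(150, bool)
        usable[10] = False
        bins = bins.with_usable(usable)
        rng = np.random.default_rng(3)
        bcm = ct.BinCountMatrix(
            bins=bins,
            counts=rng.poisson(100, (150, 1)),
            cells=pd.DataFrame({"cell_id": ["a"], "label": "green", "mouse": "M1"}),
        )
        prof = ct.gc_normalize(bcm)
        assert np.isnan(prof.ratios[10, 0])
        assert not np.isnan(np.delete(prof.ratios[:, 0], 10)).any()
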