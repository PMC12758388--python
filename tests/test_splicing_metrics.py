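"""SPI, differential SPI, intron categories, and F_UPFI."""

import numpy as np
import pytest
from scipy import stats as sps

from exonblocks.block_caller import SignificanceThresholds, call_blocks
from exonblocks.core_model import GenomicInterval
from exonblocks.io_formats import RawAlignment
from exonblocks.read_ops import reconstruct_geometry
from exonblocks.splicing_metrics import (
    IntronCategory,
    SPIRecord,
    categorize_introns,
    compute_fupfi,
    compute_spi,
    differential_spi,
    spi_histograms,
)

from conftest import geometry, make_model, make_record


INTRON = GenomicInterval("chr1", 300, 800)


def spliced_read(i, intron=INTRON):
    return reconstruct_geometry(
        RawAlignment(f"s{i}", 0, intron.chrom, intron.start - 20,
                     f"20M{len(intron)}N20M")
    )


def unspliced_read(i, boundary=INTRON.start, chrom="chr1"):
    return reconstruct_geometry(
        RawAlignment(f"u{i}", 0, chrom, boundary - 20, "40M")
    )


class TestComputeSPI:
    def test_ratio(self):
        reads = [spliced_read(i) for i in range(90)] + [
            unspliced_read(i) for i in range(10)
        ]
        rec = compute_spi(INTRON, reads)
        assert rec.spi == pytest.approx(0.9)

    def test_fully_unspliced(self):
        reads = [unspliced_read(i) for i in range(50)]
        assert compute_spi(INTRON, reads).spi == 0.0

    def test_low_coverage_flagged(self):
        reads = [spliced_read(i) for i in range(4)] + [
            unspliced_read(i) for i in range(3)
        ]
        rec = compute_spi(INTRON, reads, min_cov=10)
        assert rec.low_coverage and rec.spi is None

    def test_overhang_requirement(self):
        # read ends 2 nt past the boundary: below the 3 nt overhang
        short = reconstruct_geometry(
            RawAlignment("x", 0, "chr1", INTRON.start - 20, "22M")
        )
        rec = compute_spi(INTRON, [short], min_cov=1)
        assert rec.total == 0

    def test_both_boundaries_pooled(self):
        reads = [unspliced_read(0, INTRON.start), unspliced_read(1, INTRON.end)]
        rec = compute_spi(INTRON, reads, min_cov=1)
        assert rec.unspliced_reads == 2

    def test_recovery_within_binomial_error(self):
        """|SPI - truth| <= 3 binomial SD for simulated efficiencies."""
        rng = np.random.default_rng(17)
        failures = 0
        trials = 60
        for e in (0.1, 0.5, 0.9):
            for _ in range(trials // 3):
                n = 100
                k = rng.binomial(n, e)
                reads = [spliced_read(i) for i in range(k)] + [
                    unspliced_read(i) for i in range(n - k)
                ]
                spi = compute_spi(INTRON, reads).spi
                sd = np.sqrt(e * (1 - e) / n)
                if abs(spi - e) > 3 * sd:
                    failures += 1
        assert failures / trials <= 0.05


def spi_rec(spliced, unspliced, condition):
    total = spliced + unspliced
    return SPIRecord(
        intron=INTRON, spliced_reads=spliced, unspliced_reads=unspliced,
        spi=spliced / total, low_coverage=total < 10, condition=condition,
    )


def fisher_oracle(table):
    """Exact two-sided Fisher p by hypergeometric enumeration."""
    (a, b), (c, d) = table
    n = a + b + c + d
    row1, col1 = a + b, a + c
    rv = sps.hypergeom(n, row1, col1)
    p_obs = rv.pmf(a)
    return sum(
        rv.pmf(k)
        for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1)
        if rv.pmf(k) <= p_obs * (1 + 1e-9)
    )


class TestDifferentialSPI:
    def test_large_shift_significant_fisher_branch(self):
        # small cells: 4 unspliced in treatment forces the exact test
        diff = differential_spi(
            [spi_rec(50, 50, "ctrl")], [spi_rec(96, 4, "treat")]
        )
        assert diff.delta_spi == pytest.approx(0.46)
        assert diff.p_value == pytest.approx(
            fisher_oracle([[50, 50], [96, 4]]), rel=1e-6
        )
        assert diff.significant

    def test_identical_counts_fisher_p_one(self):
        diff = differential_spi(
            [spi_rec(4, 9, "ctrl")], [spi_rec(4, 9, "treat")]
        )
        assert diff.delta_spi == 0.0
        assert diff.p_value == pytest.approx(1.0)
        assert not diff.significant

    def test_small_delta_not_significant_despite_tiny_p(self):
        diff = differential_spi(
            [spi_rec(5000, 5000, "ctrl")], [spi_rec(5800, 4200, "treat")]
        )
        assert diff.p_value < 1e-10
        assert abs(diff.delta_spi) < 0.10
        assert not diff.significant

    def test_low_coverage_excluded(self):
        out = differential_spi(
            [spi_rec(3, 2, "ctrl")], [spi_rec(50, 50, "treat")]
        )
        assert out is None

    def test_replicate_means(self):
        diff = differential_spi(
            [spi_rec(80, 20, "ctrl"), spi_rec(60, 40, "ctrl")],
            [spi_rec(90, 10, "treat"), spi_rec(90, 10, "treat")],
        )
        assert diff.spi_ctrl == pytest.approx(0.7)
        assert diff.delta_spi == pytest.approx(0.2)


class TestCategorizeIntrons:
    def _blocks(self, model, runs):
        out = []
        for run in runs:
            recs = [make_record("g1", i, -0.2 - 0.001 * j)
                    for j, i in enumerate(run)]
            b, _ = call_blocks(recs, model, SignificanceThresholds())
            out += b
        return out

    def test_three_exon_block_internal_and_flanking(self):
        model = make_model([(i * 300, i * 300 + 100) for i in range(1, 8)])
        blocks = self._blocks(model, [[2, 3, 4]])
        labels = categorize_introns(blocks, {"g1": model})
        assert labels[("g1", 2)] == IntronCategory.BLOCK_INTERNAL
        assert labels[("g1", 3)] == IntronCategory.BLOCK_INTERNAL
        assert labels[("g1", 1)] == IntronCategory.BLOCK_FLANKING
        assert labels[("g1", 4)] == IntronCategory.BLOCK_FLANKING
        assert labels[("g1", 0)] == IntronCategory.OTHER

    def test_gene_without_blocks_all_other(self):
        model = make_model([(i * 300, i * 300 + 100) for i in range(1, 5)])
        labels = categorize_introns([], {"g1": model})
        assert set(labels.values()) == {IntronCategory.OTHER}

    def test_partition_is_complete(self):
        model = make_model([(i * 300, i * 300 + 100) for i in range(1, 8)])
        blocks = self._blocks(model, [[2, 3]])
        labels = categorize_introns(blocks, {"g1": model})
        assert set(labels) == {("g1", i) for i in range(6)}

    def test_shared_intron_between_adjacent_blocks_single_label(self):
        # blocks [1,2] and [4,5]: intron 3 flanks both -> one flanking label
        model = make_model([(i * 300, i * 300 + 100) for i in range(1, 8)])
        blocks = self._blocks(model, [[1, 2], [4, 5]])
        labels = categorize_introns(blocks, {"g1": model})
        assert labels[("g1", 3)] == IntronCategory.BLOCK_FLANKING

    def test_internal_wins_over_flanking(self):
        # blocks [1,2] and [3,4]: intron 2 flanks [1,2]... but for
        # directly adjacent blocks intron 2 is between exon 2 and 3,
        # flanking both; construct overlap via a 3-exon + adjacent 2-exon
        model = make_model([(i * 300, i * 300 + 100) for i in range(1, 9)])
        blocks = self._blocks(model, [[1, 2, 3], [4, 5]])
        labels = categorize_introns(blocks, {"g1": model})
        # intron 3 (between exons 3 and 4) flanks both blocks
        assert labels[("g1", 3)] == IntronCategory.BLOCK_FLANKING
        # intron 1 and 2 internal to the first block
        assert labels[("g1", 1)] == IntronCategory.BLOCK_INTERNAL
        assert labels[("g1", 2)] == IntronCategory.BLOCK_INTERNAL


class TestHistograms:
    def _keys(self, model):
        return {
            (iv.chrom, iv.start, iv.end): ("g1", i)
            for i, iv in enumerate(model.introns)
        }

    def test_single_value_single_bin(self):
        model = make_model([(i * 300, i * 300 + 100) for i in range(1, 4)])
        rec = SPIRecord(intron=model.introns[0], spliced_reads=90,
                        unspliced_reads=10, spi=0.9, low_coverage=False)
        hists = spi_histograms(
            [rec], categorize_introns([], {"g1": model}), self._keys(model)
        )
        h = hists[IntronCategory.OTHER]
        assert h.sum() == pytest.approx(1.0)
        assert h[int(0.9 / 0.05)] == pytest.approx(1.0)

    def test_two_extremes_split_mass(self):
        model = make_model([(i * 300, i * 300 + 100) for i in range(1, 4)])
        recs = [
            SPIRecord(intron=model.introns[0], spliced_reads=0,
                      unspliced_reads=50, spi=0.0, low_coverage=False),
            SPIRecord(intron=model.introns[1], spliced_reads=50,
                      unspliced_reads=0, spi=1.0, low_coverage=False),
        ]
        hists = spi_histograms(
            recs, categorize_introns([], {"g1": model}), self._keys(model)
        )
        h = hists[IntronCategory.OTHER]
        assert h[0] == pytest.approx(0.5) and h[-1] == pytest.approx(0.5)

    def test_empty_category_all_zero(self):
        model = make_model([(i * 300, i * 300 + 100) for i in range(1, 4)])
        hists = spi_histograms(
            [], categorize_introns([], {"g1": model}), self._keys(model)
        )
        assert hists[IntronCategory.BLOCK_INTERNAL].sum() == 0.0


class TestFUPFI:
    def _model(self):
        return make_model([(100, 300), (500, 700), (900, 1100)])

    def _order_reads(self, model, exon_index, ups_first_flags):
        from exonblocks.synthetic import _order_read

        return geometry([
            _order_read(model, exon_index, up_first, f"o{i}")
            for i, up_first in enumerate(ups_first_flags)
        ])

    def test_all_upstream_first(self):
        model = self._model()
        reads = self._order_reads(model, 1, [True] * 10)
        assert compute_fupfi(1, reads, model).f_upfi == 1.0

    def test_all_downstream_first(self):
        model = self._model()
        reads = self._order_reads(model, 1, [False] * 10)
        assert compute_fupfi(1, reads, model).f_upfi == 0.0

    def test_minus_strand_orientation(self):
        model = make_model([(100, 300), (500, 700), (900, 1100)], strand="-")
        reads = self._order_reads(model, 1, [True] * 10)
        assert compute_fupfi(1, reads, model).f_upfi == 1.0

    def test_terminal_exon_raises(self):
        with pytest.raises(ValueError, match="flanking intron"):
            compute_fupfi(0, [], self._model())

    def test_below_min_informative_undefined(self):
        model = self._model()
        reads = self._order_reads(model, 1, [True] * 3)
        assert compute_fupfi(1, reads, model, min_informative=5).f_upfi is None

    def test_uninformative_reads_dropped(self):
        model = self._model()
        both_spliced = geometry([
            __import__("exonblocks.synthetic", fromlist=["x"])._template_read(
                model.exons, "t0", model.chrom, 0, np.random.default_rng(0)
            )
        ])
        rec = compute_fupfi(1, both_spliced, model, min_informative=1)
        assert rec.n_up_first == rec.n_down_first == 0

    def test_binomial_recovery_at_p07(self):
        """Estimate within 3 binomial SDs of the planted order probability."""
        rng = np.random.default_rng(29)
        model = self._model()
        p, n = 0.7, 500
        flags = rng.random(n) < p
        reads = self._order_reads(model, 1, list(flags))
        rec = compute_fupfi(1, reads, model)
        sd = np.sqrt(p * (1 - p) / n)
        assert abs(rec.f_upfi - p) <= 3 * sd
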