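"""Spike-in scaling, binned coverage vs. per-base oracle, metaprofiles."""

import numpy as np
import pytest

from conftest import ivset, random_ivset
from k4balance.genome_intervals import GenomeLayout, Interval, IntervalSet
from k4balance.spikein_chipseq import (
    BarcodePanel,
    CoverageTrack,
    SampleReads,
    binned_coverage,
    count_barcode_reads,
    metaprofile,
    read_bedgraph,
    scale_factor,
    write_bedgraph,
)
from k4balance.synthetic_data import gen_genome, gen_peaks, gen_spikein_reads


@pytest.fixture
def combined_genome():
    return GenomeLayout([("chr1", 1000), ("barcode_A", 200), ("barcode_B", 200)])


class TestBarcodeCounting:
    def test_genome_reads_excluded(self, combined_genome):
        panel = BarcodePanel(["barcode_A", "barcode_B"])
        reads = ivset(combined_genome,
                      [("barcode_A", 0, 50)] * 10 + [("chr1", 0, 50)] * 5)
        sample = SampleReads("s", 1, "reference", reads)
        counts, total = count_barcode_reads(sample, panel)
        assert counts == {"barcode_A": 10, "barcode_B": 0} and total == 10

    def test_no_barcode_reads_total_zero(self, combined_genome):
        panel = BarcodePanel(["barcode_A"])
        sample = SampleReads("s", 1, "test",
                             ivset(combined_genome, [("chr1", 0, 50)]))
        _, total = count_barcode_reads(sample, panel)
        assert total == 0
        with pytest.raises(ValueError, match="no spike-in reads"):
            scale_factor(100, total)

    def test_random_mixture_matches_tally(self, combined_genome):
        rng = np.random.default_rng(3)
        names = ["chr1", "barcode_A", "barcode_B"]
        picks = rng.choice(3, size=200)
        reads = ivset(combined_genome, [(names[k], 0, 10) for k in picks])
        sample = SampleReads("s", 1, "reference", reads)
        counts, total = count_barcode_reads(sample, BarcodePanel(["barcode_A", "barcode_B"]))
        assert counts["barcode_A"] == int((picks == 1).sum())
        assert counts["barcode_B"] == int((picks == 2).sum())
        assert total == int((picks > 0).sum())


class TestScaleFactor:
    @pytest.mark.parametrize("ref,test,expected", [(1000, 500, 2.0), (700, 700, 1.0)])
    def test_ratio(self, ref, test, expected):
        assert scale_factor(ref, test) == expected

    def test_global_signal_loss_recovered(self):
        """2x global ChIP signal loss with constant spike-in is recovered
        within 10% after scaling."""
        genome, excluded = gen_genome(seed=1)
        signal = gen_peaks(genome, excluded, n_peaks=80, seed=2)
        samples, panel, _, truth = gen_spikein_reads(
            genome, signal, n_reads=20_000,
            global_scale={"reference": 1.0, "test": 0.5}, seed=3)
        g = truth.params["global_scale"]["test"]
        for rep in (1, 2):
            ref, test = samples[("reference", rep)], samples[("test", rep)]
            _, rt = count_barcode_reads(ref, panel)
            _, tt = count_barcode_reads(test, panel)
            f = scale_factor(rt, tt)
            cov_ref = binned_coverage(ref.reads, genome, 50, 1.0)
            cov_test = binned_coverage(test.reads, genome, 50, f)
            ratio = (sum(cov_test.values[c].sum() for c in genome.names)
                     / sum(cov_ref.values[c].sum() for c in genome.names))
            assert ratio == pytest.approx(g, rel=0.10)


class TestBinnedCoverage:
    def test_single_read_bins(self):
        genome = GenomeLayout([("chr1", 100)])
        reads = ivset(genome, [("chr1", 0, 50)])
        track = binned_coverage(reads, genome, bin_size=50, scale=1.0)
        assert track.values["chr1"] == pytest.approx([1.0, 0.0])
        track2 = binned_coverage(reads, genome, bin_size=50, scale=2.0)
        assert track2.values["chr1"] == pytest.approx([2.0, 0.0])

    def test_partial_final_bin_uses_true_width(self):
        genome = GenomeLayout([("chr1", 75)])
        reads = ivset(genome, [("chr1", 50, 75)])
        track = binned_coverage(reads, genome, bin_size=50)
        # final bin is 25 bp wide, fully covered
        assert track.values["chr1"] == pytest.approx([0.0, 1.0])

    def test_matches_per_base_depth_oracle(self):
        genome = GenomeLayout([("chr1", 730), ("chr2", 410)])
        rng = np.random.default_rng(7)
        for _ in range(20):
            reads = random_ivset(genome, rng, max_n=30, max_len=90)
            bs = int(rng.integers(10, 100))
            track = binned_coverage(reads, genome, bin_size=bs, scale=1.0)
            for chrom, length in genome.chromosomes:
                depth = np.zeros(length)
                for iv in reads:
                    if iv.chrom == chrom:
                        depth[iv.start:iv.end] += 1
                nb = -(-length // bs)
                expected = [depth[b * bs:min((b + 1) * bs, length)].mean()
                            for b in range(nb)]
                assert track.values[chrom] == pytest.approx(expected)

    def test_scaling_linearity_exact(self):
        genome = GenomeLayout([("chr1", 1000)])
        rng = np.random.default_rng(1)
        reads = random_ivset(genome, rng, max_n=40, max_len=120)
        t1 = binned_coverage(reads, genome, 50, 1.0)
        t3 = binned_coverage(reads, genome, 50, 3.0)
        assert np.array_equal(3.0 * t1.values["chr1"], t3.values["chr1"])

    def test_total_signal_conservation(self):
        """sum(bin value x bin width) = scale x total read bases, exactly."""
        genome = GenomeLayout([("chr1", 730)])
        rng = np.random.default_rng(5)
        reads = random_ivset(genome, rng, max_n=30, max_len=90)
        bs = 50
        track = binned_coverage(reads, genome, bs, scale=2.5)
        nb = len(track.values["chr1"])
        widths = np.full(nb, bs, dtype=float)
        widths[-1] = 730 - (nb - 1) * bs
        total = float((track.values["chr1"] * widths).sum())
        read_bases = sum(iv.length for iv in reads)
        assert total == pytest.approx(2.5 * read_bases, rel=1e-12)


class TestMetaprofile:
    def _track(self, genome, fn):
        values = {c: np.array([fn(c, b) for b in range(-(-l // 50))], dtype=float)
                  for c, l in genome.chromosomes}
        return CoverageTrack(genome=genome, bin_size=50, values=values)

    def test_constant_track(self, toy_genome):
        track = self._track(toy_genome, lambda c, b: 3.25)
        centers = ivset(toy_genome, [("chr1", 10_000, 10_500),
                                     ("chr2", 40_000, 41_000)])
        mat, order, trunc = metaprofile(track, centers, flank=1000, n_bins=20)
        assert np.allclose(mat, 3.25)
        assert not trunc.any()

    def test_peaked_track_sorts_covering_region_first(self, toy_genome):
        peak_bin = 10_250 // 50
        track = self._track(
            toy_genome, lambda c, b: 10.0 if c == "chr1" and abs(b - peak_bin) < 5 else 0.1)
        centers = ivset(toy_genome, [("chr2", 300_000, 300_400),  # distal
                                     ("chr1", 10_000, 10_500)])   # covers peak
        mat, order, _ = metaprofile(track, centers, flank=1000, n_bins=10)
        assert order[0] == 1  # the covering region ranks first
        assert mat[0].mean() > mat[1].mean()

    def test_row_means_linear_in_scale(self, toy_genome):
        rng = np.random.default_rng(2)
        vals = {c: rng.random(-(-l // 50)) for c, l in toy_genome.chromosomes}
        t1 = CoverageTrack(toy_genome, 50, vals)
        t4 = CoverageTrack(toy_genome, 50, {c: 4.0 * v for c, v in vals.items()})
        centers = ivset(toy_genome, [("chr1", 5000, 5400), ("chr2", 9000, 9600)])
        m1, _, _ = metaprofile(t1, centers, flank=500, n_bins=8)
        m4, _, _ = metaprofile(t4, centers, flank=500, n_bins=8)
        assert np.allclose(m4, 4.0 * m1)

    def test_edge_truncation_flagged_and_zero_padded(self, toy_genome):
        track = self._track(toy_genome, lambda c, b: 1.0)
        centers = ivset(toy_genome, [("chr1", 0, 100)])  # window leaves chromosome
        mat, _, trunc = metaprofile(track, centers, flank=1000, n_bins=4)
        assert trunc[0]
        assert mat[0, 0] < 1.0  # left bins partially zero-padded

    def test_unknown_chromosome_rejected(self, toy_genome):
        track = self._track(toy_genome, lambda c, b: 1.0)
        g = GenomeLayout([("chrZ", 5000)])
        bad = IntervalSet([Interval("chrZ", 2000, 2100)], g)
        with pytest.raises(ValueError, match="unknown chromosome"):
            metaprofile(track, bad, flank=100, n_bins=2)


class TestBedGraphIO:
    def test_round_trip(self, tmp_path):
        genome = GenomeLayout([("chr1", 230), ("chr2", 100)])
        rng = np.random.default_rng(0)
        reads = random_ivset(genome, rng, max_n=20, max_len=50)
        track = binned_coverage(reads, genome, 50, 1.5)
        p = tmp_path / "t.bedGraph"
        write_bedgraph(track, p)
        back = read_bedgraph(p, genome, 50)
        for c in genome.names:
            assert back.values[c] == pytest.approx(track.values[c], rel=1e-9)
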