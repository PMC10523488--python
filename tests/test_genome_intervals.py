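"""Interval model, BED I/O, and exact set arithmetic vs. a per-base oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import basemask, ivset, random_ivset
from k4balance.genome_intervals import (
    BedParseError,
    GenomeLayout,
    GenomeMismatchError,
    Interval,
    IntervalSet,
    complement,
    fisher_overlap,
    merge,
    overlap_bp,
    read_bed,
    read_chrom_sizes,
    subtract,
    total_bp,
    write_bed,
)


class TestModel:
    def test_layout_invariants(self):
        g = GenomeLayout([("chr1", 100), ("chr2", 50)])
        assert g.total_size == 150
        assert g.names == ("chr1", "chr2")
        with pytest.raises(ValueError, match="unique"):
            GenomeLayout([("chr1", 100), ("chr1", 50)])
        with pytest.raises(ValueError, match="non-positive"):
            GenomeLayout([("chr1", 0)])

    @pytest.mark.parametrize("start,end", [(-1, 5), (5, 5), (7, 3)])
    def test_interval_rejects_degenerate(self, start, end):
        with pytest.raises(ValueError):
            Interval("chr1", start, end)

    def test_set_validates_against_genome(self, small_genome):
        with pytest.raises(ValueError, match="unknown chromosome"):
            IntervalSet([Interval("chrX", 0, 10)], small_genome)
        with pytest.raises(ValueError, match="exceeds"):
            IntervalSet([Interval("chr1", 990, 1010)], small_genome)


class TestBedIO:
    def test_parse_simple(self, tmp_path, small_genome):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t10\n")
        s = read_bed(p, small_genome)
        assert len(s) == 1 and s[0].start == 0 and s[0].end == 10

    def test_zero_length_is_parse_error(self, tmp_path, small_genome):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t10\t10\n")
        with pytest.raises(BedParseError, match="line 1"):
            read_bed(p, small_genome)

    def test_non_integer_coordinates(self, tmp_path, small_genome):
        p = tmp_path / "a.bed"
        p.write_text("chr1\tten\t20\n")
        with pytest.raises(BedParseError, match="non-integer"):
            read_bed(p, small_genome)

    def test_unknown_chromosome_named_in_error(self, tmp_path, small_genome):
        p = tmp_path / "a.bed"
        p.write_text("chrZ\t0\t10\n")
        with pytest.raises(ValueError, match="chrZ"):
            read_bed(p, small_genome)

    def test_mixed_3_and_6_column_records(self, tmp_path, small_genome):
        p = tmp_path / "a.bed"
        p.write_text("track name=x\n# comment\nchr1\t0\t10\n"
                     "chr2\t5\t25\tpeakA\t3.5\t+\n")
        s = read_bed(p, small_genome)
        assert len(s) == 2
        assert s[0].name is None and s[0].strand is None
        assert s[1].name == "peakA" and s[1].score == 3.5 and s[1].strand == "+"

    def test_round_trip_bit_exact(self, tmp_path, small_genome):
        ivs = IntervalSet(
            [Interval("chr1", 3, 99, name="a", score=1.25, strand="-"),
             Interval("chr2", 0, 1000)],
            small_genome,
        )
        p = tmp_path / "out.bed"
        write_bed(ivs, p)
        back = read_bed(p, small_genome)
        assert [(i.chrom, i.start, i.end, i.name, i.score, i.strand) for i in back] == \
               [(i.chrom, i.start, i.end, i.name, i.score, i.strand) for i in ivs]

    def test_chrom_sizes(self, tmp_path):
        p = tmp_path / "g.sizes"
        p.write_text("chr1\t100\nchr2\t200\n")
        g = read_chrom_sizes(p)
        assert g.lengths == {"chr1": 100, "chr2": 200}


class TestSetAlgebra:
    def test_merge_overlapping(self, small_genome):
        assert [(i.start, i.end) for i in merge(ivset(small_genome,
                [("chr1", 0, 10), ("chr1", 5, 15)]))] == [(0, 15)]

    def test_merge_book_ended(self, small_genome):
        assert [(i.start, i.end) for i in merge(ivset(small_genome,
                [("chr1", 0, 5), ("chr1", 5, 10)]))] == [(0, 10)]

    def test_merge_disjoint_sorted_identity(self, small_genome):
        s = ivset(small_genome, [("chr2", 5, 9), ("chr1", 0, 3), ("chr1", 10, 12)])
        m = merge(s)
        assert [(i.chrom, i.start, i.end) for i in m] == \
               [("chr1", 0, 3), ("chr1", 10, 12), ("chr2", 5, 9)]
        # idempotent
        assert [(i.chrom, i.start, i.end) for i in merge(m)] == \
               [(i.chrom, i.start, i.end) for i in m]

    def test_overlap_simple_and_identity(self, small_genome):
        a = ivset(small_genome, [("chr1", 0, 10)])
        b = ivset(small_genome, [("chr1", 5, 15)])
        assert overlap_bp(a, b) == 5
        assert overlap_bp(a, a) == total_bp(a) == 10

    def test_book_ended_overlap_is_zero(self, small_genome):
        a = ivset(small_genome, [("chr1", 0, 5)])
        b = ivset(small_genome, [("chr1", 5, 10)])
        assert overlap_bp(a, b) == 0

    def test_genome_mismatch_rejected(self, small_genome):
        other = GenomeLayout([("chr1", 2000)])
        a = ivset(small_genome, [("chr1", 0, 10)])
        b = IntervalSet([Interval("chr1", 0, 10)], other)
        with pytest.raises(GenomeMismatchError):
            overlap_bp(a, b)

    def test_subtract_splits(self, small_genome):
        a = ivset(small_genome, [("chr1", 0, 10)])
        excl = ivset(small_genome, [("chr1", 3, 6)])
        assert [(i.start, i.end) for i in subtract(a, excl)] == [(0, 3), (6, 10)]

    def test_subtract_empty_exclusion_is_merge(self, small_genome):
        a = ivset(small_genome, [("chr1", 5, 15), ("chr1", 0, 10)])
        out = subtract(a, IntervalSet([], small_genome))
        assert [(i.start, i.end) for i in out] == [(0, 15)]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_algebra_matches_per_base_oracle(self, seed):
        """merge / overlap_bp / subtract agree with boolean-array arithmetic."""
        genome = GenomeLayout([("chr1", 700), ("chr2", 300)])
        rng = np.random.default_rng(seed)
        a, b = random_ivset(genome, rng), random_ivset(genome, rng)
        ma, mb = basemask(a), basemask(b)
        assert overlap_bp(a, b) == sum(int((ma[c] & mb[c]).sum()) for c in ma)
        assert overlap_bp(a, b) == overlap_bp(b, a)
        assert overlap_bp(a, b) <= min(total_bp(a), total_bp(b))
        assert total_bp(merge(a)) == sum(int(m.sum()) for m in ma.values())
        sub = subtract(a, b)
        msub = basemask(sub)
        for c in ma:
            assert np.array_equal(msub[c], ma[c] & ~mb[c])
        assert all(iv.length > 0 for iv in sub)

    def test_complement_partitions_genome(self, small_genome):
        a = ivset(small_genome, [("chr1", 100, 400), ("chr2", 0, 1000)])
        assert total_bp(a) + total_bp(complement(a)) == small_genome.total_size


class TestFisherOverlap:
    def test_identical_sets_strongly_associated(self, toy_genome):
        rng = np.random.default_rng(0)
        a = merge(random_ivset(toy_genome, rng, max_n=30, max_len=500))
        table, p = fisher_overlap(a, a, toy_genome)
        assert table[0, 1] == 0 and table[1, 0] == 0  # no a-only, no b-only
        assert p < 0.05

    def test_p_matches_hypergeometric_tail_enumeration(self):
        """Two-sided Fisher p equals the sum of table probabilities <= observed."""
        from math import comb
        table = np.array([[10, 2], [3, 85]])
        r1, r2 = table[0].sum(), table[1].sum()
        c1 = table[:, 0].sum()
        n = table.sum()
        def prob(k):  # P(top-left = k) under fixed margins
            return comb(r1, k) * comb(r2, c1 - k) / comb(n, c1)
        p_obs = prob(10)
        expected = sum(prob(k) for k in range(max(0, c1 - r2), min(r1, c1) + 1)
                       if prob(k) <= p_obs * (1 + 1e-9))
        from scipy.stats import fisher_exact
        _, p = fisher_exact(table)
        assert p == pytest.approx(expected, rel=1e-9)

    def test_independent_sets_p_not_degenerate(self, toy_genome):
        """Independently placed sparse sets: p is rarely tiny."""
        small = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            a = random_ivset(toy_genome, rng, max_n=20, max_len=400)
            b = random_ivset(toy_genome, rng, max_n=20, max_len=400)
            _, p = fisher_overlap(a, b, toy_genome)
            small += p < 0.05
        assert small < 20  # not concentrated near 0

    def test_empty_input_rejected(self, small_genome):
        a = ivset(small_genome, [("chr1", 0, 10)])
        with pytest.raises(ValueError):
            fisher_overlap(a, IntervalSet([], small_genome), small_genome)
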