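"""Length-normalized positions, tenth partitions, 5'-overlap calls and
nucleotide frequency matrices."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from asmapper.analytics import (five_prime_overlap, frequency_matrix,
                                partition_index, position_histogram,
                                relative_position)
from asmapper.model import AsRnaLocus, Gene, Tss


class TestRelativePosition:
    gene_plus = Gene("g", "chr", 1000, 1101, "+")   # L = 101
    gene_minus = Gene("g", "chr", 1000, 1101, "-")

    @pytest.mark.parametrize("gene,pos,expected", [
        (gene_plus, 1000, 0.0),
        (gene_plus, 1050, 50.0),
        (gene_plus, 1100, 100.0),
        (gene_minus, 1100, 0.0),   # first base in gene orientation
        (gene_minus, 1000, 100.0),
        (gene_minus, 1050, 50.0),
    ])
    def test_normalized_scale(self, gene, pos, expected):
        assert relative_position(pos, gene) == pytest.approx(expected)

    def test_outside_gene_rejected(self):
        with pytest.raises(ValueError):
            relative_position(999, self.gene_plus)
        with pytest.raises(ValueError):
            relative_position(1101, self.gene_plus)

    def test_orientation_equivariance(self):
        """Mirroring the genome and flipping strands leaves d unchanged."""
        L = 5000
        rng = np.random.default_rng(3)
        for _ in range(50):
            start = int(rng.integers(0, 4000))
            length = int(rng.integers(2, 900))
            pos = int(rng.integers(start, start + length))
            g = Gene("g", "chr", start, start + length, "+")
            g_mirror = Gene("g", "chr", L - (start + length), L - start, "-")
            assert relative_position(pos, g) == pytest.approx(
                relative_position(L - 1 - pos, g_mirror))


class TestPartition:
    @pytest.mark.parametrize("d,expected", [
        (0.0, 0), (9.999, 0), (10.0, 1), (50.0, 5), (95.0, 9),
        (99.9, 9), (100.0, 9),  # d = 100 clamps into the last tenth
    ])
    def test_tenths(self, d, expected):
        assert partition_index(d) == expected

    def test_agrees_with_interval_scan_on_grid(self):
        intervals = [(10 * i, 10 * (i + 1)) for i in range(10)]
        for d in np.arange(0, 100.1, 0.1):
            d = float(round(d, 1))
            brute = next(i for i, (lo, hi) in enumerate(intervals)
                         if lo <= d < hi or (i == 9 and d == 100.0))
            assert partition_index(d) == brute, d

    def test_out_of_range_rejected(self):
        for d in (-0.1, 100.1):
            with pytest.raises(ValueError):
                partition_index(d)


class TestFivePrimeOverlap:
    gene = Gene("g", "chr", 1000, 2000, "+")  # window [1000, 1015)

    def _locus(self, start, end):
        return AsRnaLocus("as_1", "aTSS_1", "chr", start, end, "-")

    @pytest.mark.parametrize("start,end,expected", [
        (990, 1010, True),
        (1020, 1100, False),
        (900, 1000, False),   # half-open: no shared base
        (1014, 1200, True),   # last window base
        (1015, 1200, False),
    ])
    def test_window_intersection(self, start, end, expected):
        assert five_prime_overlap(self._locus(start, end), self.gene) is expected

    def test_minus_strand_gene_window_at_interval_end(self):
        gene = Gene("g", "chr", 1000, 2000, "-")  # window [1985, 2000)
        assert five_prime_overlap(self._locus(1990, 2010), gene)
        assert not five_prime_overlap(self._locus(1900, 1985), gene)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(900, 1200), st.integers(1, 300), st.integers(0, 40))
    def test_monotone_in_extension(self, start, size, ext):
        locus = self._locus(start, start + size)
        if five_prime_overlap(locus, self.gene, ext):
            assert five_prime_overlap(locus, self.gene, ext + 7)


class TestFrequencyMatrix:
    def test_uniform_genome_gives_unit_frequency(self):
        fm = frequency_matrix([("chr", 50, "+")], {"chr": "G" * 100},
                              list(range(-40, 11)))
        assert np.all(fm.frequencies[:, 2] == 1.0)  # G column

    def test_minus_strand_site_is_reverse_complemented(self):
        fm = frequency_matrix([("chr", 50, "-")], {"chr": "G" * 100},
                              list(range(-10, 11)))
        assert np.all(fm.frequencies[:, 1] == 1.0)  # C column

    def test_mixed_sites_split_frequencies(self):
        genome = {"chr": "G" * 50 + "A" + "G" * 49}
        fm = frequency_matrix([("chr", 50, "+"), ("chr", 30, "+")], genome,
                              [0])
        assert fm.frequencies[0, 0] == 0.5 and fm.frequencies[0, 2] == 0.5

    def test_columns_sum_to_one_where_sites_contribute(self):
        rng = np.random.default_rng(5)
        genome = {"chr": "".join(rng.choice(list("ACGT"), size=500))}
        sites = [("chr", int(p), str(s)) for p, s in
                 zip(rng.integers(100, 400, 30), rng.choice(["+", "-"], 30))]
        fm = frequency_matrix(sites, genome, list(range(-20, 21)))
        sums = fm.frequencies.sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_out_of_bounds_site_skipped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            fm = frequency_matrix([("chr", 2, "+"), ("chr", 50, "+")],
                                  {"chr": "G" * 100}, list(range(-10, 11)))
        assert fm.n_sites == 1
        assert "out of bounds" in caplog.text

    def test_empty_site_list_rejected(self):
        with pytest.raises(ValueError):
            frequency_matrix([], {"chr": "G" * 100}, [0])


class TestPositionHistogram:
    def test_midpoint_lands_in_partition_five(self):
        gene = Gene("g", "chr", 1000, 1101, "+")
        site = Tss("aTSS_1", "chr", 1050, "-", "antisense", ["g"])
        hist = position_histogram([site], {"g": gene})
        assert hist[5] == 1 and hist.sum() == 1

    def test_empty_input_gives_zero_histogram(self):
        assert position_histogram([], {}).sum() == 0

    def test_uniform_placement_is_multinomial(self):
        from scipy.stats import chisquare

        rng = np.random.default_rng(8)
        gene = Gene("g", "chr", 0, 1001, "+")  # offsets 0..1000
        sites = [Tss(f"aTSS_{i}", "chr", int(p), "-", "antisense", ["g"])
                 for i, p in enumerate(rng.integers(0, 1001, size=10000))]
        hist = position_histogram(sites, {"g": gene})
        assert hist.sum() == 10000
        # exact bin probabilities: 100 offsets per tenth, 101 in the last
        # (d = 100 clamps into partition 9)
        probs = np.array([100] * 9 + [101]) / 1001
        result = chisquare(hist, f_exp=10000 * probs)
        assert result.pvalue > 1e-6

    def test_two_gene_site_counts_once_per_gene(self):
        g1 = Gene("g1", "chr", 1000, 2001, "+")
        g2 = Gene("g2", "chr", 1800, 2401, "+")
        site = Tss("aTSS_1", "chr", 1900, "-", "antisense", ["g1", "g2"])
        hist = position_histogram([site], {"g1": g1, "g2": g2})
        assert hist.sum() == 2
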