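"""Folding score semantics, genome tiling arithmetic, quantile cutoff and
the structure filter's partition behaviour."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from asmapper.model import Tss
from asmapper.structure import (MfeWindow, downstream_window,
                                filter_structured_atss, fold_energy,
                                get_folder, mfe_cutoff, tile_genome_mfe)

PAIR_WEIGHT = {("G", "C"): 3, ("C", "G"): 3, ("A", "U"): 2, ("U", "A"): 2,
               ("G", "U"): 1, ("U", "G"): 1}


def enumerate_best_pairing(seq):
    """Independent oracle: enumerate every nested structure recursively
    (minimum hairpin loop 3) and return the maximal total pair weight."""

    def best(i, j):
        if j - i < 4:
            return 0
        score = best(i + 1, j)  # i unpaired
        for k in range(i + 4, j + 1):
            w = PAIR_WEIGHT.get((seq[i], seq[k]))
            if w:
                score = max(score, w + best(i + 1, k - 1) + best(k + 1, j))
        return score

    return best(0, len(seq) - 1)


class TestFoldEnergy:
    @pytest.mark.parametrize("seq,expected", [
        ("AAAAAA", 0.0),      # no complementary pairs
        ("GAAAC", -3.0),      # single GC pair over a 3-nt loop
        ("GGGAAACCC", -9.0),  # three stacked GC pairs
        ("A", 0.0),
        ("GAAC", 0.0),        # loop would be 2 nt: no pair allowed
    ])
    def test_reference_values(self, seq, expected):
        assert fold_energy(seq) == expected

    def test_t_maps_to_u(self):
        assert fold_energy("GAAAC") == fold_energy("GAAAC".replace("U", "T"))
        assert fold_energy("GTTTTC") == fold_energy("GUUUUC")

    def test_non_nucleotide_rejected(self):
        with pytest.raises(ValueError, match="non-nucleotide"):
            fold_energy("GANAC")
        with pytest.raises(ValueError):
            fold_energy("")

    def test_matches_enumeration_on_gc_strings(self):
        for n in range(1, 7):
            for seq in map("".join, itertools.product("GC", repeat=n)):
                assert fold_energy(seq) == -enumerate_best_pairing(seq), seq

    def test_matches_enumeration_on_random_sequences(self):
        rng = np.random.default_rng(404)
        bases = np.array(list("ACGU"))
        for _ in range(100):
            n = int(rng.integers(1, 11))
            seq = "".join(rng.choice(bases, size=n))
            assert fold_energy(seq) == -enumerate_best_pairing(seq), seq

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.text(alphabet="ACGU", min_size=1, max_size=40))
    def test_energy_is_never_positive(self, seq):
        assert fold_energy(seq) <= 0.0

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.text(alphabet="ACGU", min_size=3, max_size=30))
    def test_closing_pair_never_raises_energy(self, core):
        # G...C adds an available GC pair with an adequate loop
        assert fold_energy("G" + core + "C") <= fold_energy(core)

    def test_vienna_engine_is_available_and_sane(self):
        vienna = get_folder("vienna")
        assert vienna("GGGGGAAAACCCCC") < -5.0
        assert vienna("AAAAAAAAAA") == 0.0


class TestTiling:
    def test_window_start_arithmetic(self):
        genome = {"chr": "A" * 71}
        windows = tile_genome_mfe(genome, window=51, offset=10, folder="builtin")
        starts = sorted({w.start for w in windows})
        assert starts == [0, 10, 20]  # 20+51=71 fits, 30+51=81 does not
        assert len(windows) == 6  # three per strand

    def test_replicon_shorter_than_window_yields_nothing(self):
        assert tile_genome_mfe({"chr": "A" * 50}, folder="builtin") == []

    def test_homopolymer_genome_folds_to_zero(self):
        windows = tile_genome_mfe({"chr": "A" * 200}, folder="builtin")
        assert all(w.mfe == 0.0 for w in windows)

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            tile_genome_mfe({}, folder="builtin")
        with pytest.raises(ValueError):
            tile_genome_mfe({"chr": ""}, folder="builtin")


class TestCutoff:
    def test_linear_interpolation_tertile(self):
        assert mfe_cutoff([-9, -6, -3], q=1 / 3) == -7.0

    def test_constant_distribution(self):
        assert mfe_cutoff([-4.2] * 10) == -4.2

    def test_q_zero_is_minimum(self):
        assert mfe_cutoff([-9, -6, -3], q=1e-12) == pytest.approx(-9.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mfe_cutoff([])


class TestFilter:
    def _tss(self, pos, strand="+"):
        return Tss(id=f"aTSS_{pos}", replicon="chr", position=pos,
                   strand=strand, tss_class="antisense")

    def test_unstructured_window_retained(self):
        genome = {"chr": "A" * 200}
        retained, removed = filter_structured_atss(
            [self._tss(10)], genome, cutoff=-7.0, folder="builtin")
        assert len(retained) == 1 and removed == []

    def test_structured_window_removed(self):
        seq = "GGGAAACCC" + "A" * 191  # window at 0 folds to -9 <= -7
        retained, removed = filter_structured_atss(
            [self._tss(0)], genome={"chr": seq}, cutoff=-7.0, folder="builtin")
        assert retained == [] and len(removed) == 1

    def test_minus_strand_window_is_reverse_complement(self):
        # revcomp of the 51 bases ending at position 100 must fold
        seq = "A" * 50 + "GGGTTTCCC" + "A" * 141  # revcomp contains GGGAAACCC
        tss = self._tss(100, strand="-")
        win = downstream_window({"chr": seq}, tss, 51)
        assert "GGGAAACCC" in win.replace("T", "U") or "GGGAAACCC" in win
        _, removed = filter_structured_atss([tss], {"chr": seq}, cutoff=-7.0,
                                            folder="builtin")
        assert len(removed) == 1

    def test_partition_is_exhaustive_and_disjoint(self):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        sites = [self._tss(int(p), s) for p, s in
                 zip(rng.integers(0, 2000, size=40), rng.choice(["+", "-"], 40))]
        retained, removed = filter_structured_atss(sites, {"chr": seq},
                                                   cutoff=-20.0, folder="builtin")
        assert len(retained) + len(removed) == len(sites)
        assert not ({id(t) for t in retained} & {id(t) for t in removed})

    def test_tss_near_replicon_end_retained_with_warning(self, caplog):
        genome = {"chr": "G" * 100}
        with caplog.at_level("WARNING"):
            retained, removed = filter_structured_atss(
                [self._tss(60)], genome, cutoff=-1000.0, folder="builtin")
        assert len(retained) == 1 and removed == []
        assert "insufficient sequence" in caplog.text
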