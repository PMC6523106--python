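"""Minimum-3'-end inference: thresholds, library support, orientation
symmetry and locus bookkeeping."""

import numpy as np
import pytest

from asmapper.loci import build_loci, infer_locus
from asmapper.model import PipelineConfig, ProfileTrack

from .conftest import make_track, make_tss

N = 400


def tracks_for(three_prime_counts, coverage_interval, n_cov_libs=4,
               strand="+", n=N):
    """One pooled-equivalent 3' track plus per-library coverage tracks."""
    tp = np.zeros(n, dtype=np.int64)
    for pos, v in three_prime_counts.items():
        tp[pos] = v
    cov = np.zeros(n, dtype=np.int64)
    cov[coverage_interval[0]:coverage_interval[1]] = 1
    three = [make_track(tp, strand=strand, kind="three_prime")]
    coverage = [make_track(cov, strand=strand, kind="coverage", lib=f"lib{i}")
                for i in range(n_cov_libs)]
    return three, coverage


class TestInferLocus:
    def test_first_qualifying_end_demarcates_locus(self):
        three, cov = tracks_for({219: 12}, (100, 220))
        locus = infer_locus(make_tss(100), three, cov)
        assert (locus.start, locus.end, locus.size_nt) == (100, 220, 120)
        assert locus.end_support == 12 and locus.lib_support == 4

    def test_end_support_below_threshold_gives_no_locus(self):
        three, cov = tracks_for({219: 9}, (100, 220))
        assert infer_locus(make_tss(100), three, cov) is None

    def test_three_library_support_is_insufficient(self):
        three, cov = tracks_for({219: 12}, (100, 220), n_cov_libs=3)
        assert infer_locus(make_tss(100), three, cov) is None

    def test_minimum_end_wins_when_two_qualify(self):
        three, cov = tracks_for({180: 15, 219: 12}, (100, 220))
        locus = infer_locus(make_tss(100), three, cov)
        assert locus.end == 181

    def test_pooling_across_libraries_reaches_threshold(self):
        # 4 libraries contributing 3 observations each: pooled 12 >= 10
        tp = np.zeros(N, dtype=np.int64)
        tp[219] = 3
        three = [make_track(tp, kind="three_prime", lib=f"lib{i}")
                 for i in range(4)]
        cov = np.zeros(N, dtype=np.int64)
        cov[100:220] = 1
        coverage = [make_track(cov, kind="coverage", lib=f"lib{i}")
                    for i in range(4)]
        locus = infer_locus(make_tss(100), three, coverage)
        assert locus is not None and locus.end_support == 12

    def test_coverage_gap_breaks_library_support(self):
        three, cov = tracks_for({219: 12}, (100, 220))
        for track in cov[:1]:
            track.values[150] = 0  # gap in one library: 3 remain
        assert infer_locus(make_tss(100), three, cov) is None

    def test_minus_strand_mirrors_plus(self):
        # + case: TSS 100 -> end at 219
        three_p, cov_p = tracks_for({219: 12}, (100, 220))
        plus = infer_locus(make_tss(100), three_p, cov_p)
        # mirrored - case: TSS at N-101, 3' signal at N-220
        three_m, cov_m = tracks_for({N - 220: 12}, (N - 220, N - 100),
                                    strand="-")
        minus = infer_locus(make_tss(N - 101, strand="-"), three_m, cov_m)
        assert minus is not None
        assert minus.size_nt == plus.size_nt == 120
        assert (minus.start, minus.end) == (N - 220, N - 100)
        assert minus.tss_position == N - 101

    def test_added_downstream_signal_never_extends_existing_end(self):
        three, cov = tracks_for({180: 15}, (100, 300))
        before = infer_locus(make_tss(100), three, cov)
        three[0].values[260] = 50
        after = infer_locus(make_tss(100), three, cov)
        assert after.end == before.end == 181

    def test_scan_is_bounded_by_max_span(self):
        cfg = PipelineConfig(max_locus_span_nt=50)
        three, cov = tracks_for({219: 12}, (100, 220))
        assert infer_locus(make_tss(100), three, cov, cfg) is None

    def test_mismatched_strand_rejected(self):
        three, cov = tracks_for({219: 12}, (100, 220))
        with pytest.raises(ValueError):
            infer_locus(make_tss(100, strand="-"), three, cov)


class TestBuildLoci:
    def test_empty_input_gives_empty_output(self):
        three, cov = tracks_for({}, (0, 0))
        assert build_loci([], three, cov) == []

    def test_id_follows_naming_convention(self):
        three, cov = tracks_for({219: 12}, (100, 220))
        sites = [make_tss(100, tss_id="aTSS_7", cognates=["VNG_RS00125"])]
        (locus,) = build_loci(sites, three, cov)
        assert locus.asrna_id == "VNG_as00125_7"
        assert locus.tss_id == "aTSS_7"

    def test_locus_overlapping_second_gene_gains_cognate(self):
        from asmapper.model import Gene

        genes = [Gene("VNG_RS00105", "chr", 150, 300, "-"),
                 Gene("VNG_RS00110", "chr", 60, 140, "-")]
        three, cov = tracks_for({219: 12}, (100, 220))
        sites = [make_tss(100, tss_id="daTSS_3", cognates=["VNG_RS00110"],
                          tss_class="downstream_antisense")]
        (locus,) = build_loci(sites, three, cov, genes=genes)
        assert locus.cognate_genes == ["VNG_RS00110", "VNG_RS00105"]
        assert locus.asrna_id == "VNG_da00110_3"

    def test_emitted_loci_satisfy_invariants(self, clean_dataset):
        from asmapper.model import ANTISENSE, PipelineConfig, Tss

        ds = clean_dataset
        cfg = PipelineConfig()
        sites = [
            make_tss(a.tss_position, strand=a.strand, replicon="chrA",
                     tss_id=("aTSS_%d" if a.tss_class == ANTISENSE
                             else "daTSS_%d") % (i + 1),
                     tss_class=a.tss_class, cognates=a.cognate_genes)
            for i, a in enumerate(ds.truth.planted_asrnas)]
        loci = build_loci(sites, ds.three_prime, ds.coverage, cfg)
        assert loci
        for locus in loci:
            assert locus.size_nt == locus.end - locus.start >= 1
            assert locus.end_support >= cfg.min_end_support
            assert locus.lib_support >= cfg.min_lib_support
            if locus.strand == "+":
                assert locus.start == locus.tss_position
            else:
                assert locus.end - 1 == locus.tss_position
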