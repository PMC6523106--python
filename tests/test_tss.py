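"""aTSS/daTSS classification semantics and the simplified TSS caller."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from asmapper.model import (ANTISENSE, DOWNSTREAM_ANTISENSE, OTHER, Gene,
                            TssCallerParams)
from asmapper.tss import GeneIndex, call_tss, classify_tss

from .conftest import make_track


def brute_force_class(position, strand, genes, da=200):
    """Independent interval scan used as the classification oracle."""
    opp = [g for g in genes if g.strand != strand]
    inside = [g for g in opp if g.start <= position < g.end]
    if inside:
        return ANTISENSE, sorted(g.locus_tag for g in inside)
    down = []
    for g in opp:
        if g.strand == "+" and g.end <= position < g.end + da:
            down.append(g.locus_tag)
        elif g.strand == "-" and g.start - da <= position < g.start:
            down.append(g.locus_tag)
    if down:
        return DOWNSTREAM_ANTISENSE, sorted(down)
    return OTHER, []


class TestClassify:
    def test_tss_inside_opposite_strand_gene_is_antisense(self, plus_gene):
        cls, genes = classify_tss(1500, "-", [plus_gene])
        assert cls == ANTISENSE and genes == [plus_gene]

    def test_tss_within_200nt_past_gene_end_is_downstream(self, plus_gene):
        cls, genes = classify_tss(2100, "-", [plus_gene])
        assert cls == DOWNSTREAM_ANTISENSE and genes == [plus_gene]

    def test_tss_beyond_window_is_other(self, plus_gene):
        assert classify_tss(2250, "-", [plus_gene]) == (OTHER, [])

    def test_downstream_window_is_orientation_aware(self, minus_gene):
        # - strand gene: 3' end at the interval start, downstream leftwards
        cls, genes = classify_tss(900, "+", [minus_gene])
        assert cls == DOWNSTREAM_ANTISENSE and genes == [minus_gene]
        assert classify_tss(900, "-", [minus_gene]) == (OTHER, [])

    def test_same_strand_gene_never_qualifies(self, plus_gene):
        assert classify_tss(1500, "+", [plus_gene]) == (OTHER, [])

    def test_antisense_wins_over_downstream(self):
        a = Gene("g1", "chr", 1000, 2000, "+")
        b = Gene("g2", "chr", 2050, 2600, "+")
        # inside b (antisense) and 50 nt past a's 3' end (downstream):
        cls, genes = classify_tss(2050, "-", [a, b])
        assert cls == ANTISENSE and genes == [b]

    def test_two_overlapping_genes_give_two_cognates(self):
        a = Gene("g1", "chr", 1000, 2000, "+")
        b = Gene("g2", "chr", 1800, 2400, "+")
        cls, genes = classify_tss(1900, "-", [a, b])
        assert cls == ANTISENSE and [g.locus_tag for g in genes] == ["g1", "g2"]

    def test_agrees_with_brute_force_everywhere(self):
        genes = [Gene("g1", "chr", 1000, 2000, "+"),
                 Gene("g2", "chr", 2300, 2450, "-"),
                 Gene("g3", "chr", 100, 400, "-")]
        index = GeneIndex(genes)
        for strand in "+-":
            for pos in range(0, 2500):
                cls, cognate = classify_tss(pos, strand, index, 200,
                                            replicon="chr")
                exp_cls, exp_tags = brute_force_class(pos, strand, genes)
                assert (cls, sorted(g.locus_tag for g in cognate)) == \
                    (exp_cls, exp_tags), f"position {pos}{strand}"

    def test_gene_order_is_irrelevant(self, plus_gene, minus_gene):
        other = Gene("g9", "chr", 2100, 2300, "-")
        fwd = classify_tss(2150, "+", [plus_gene, other])
        rev = classify_tss(2150, "+", [other, plus_gene])
        assert fwd == rev

    def test_position_outside_replicon_rejected(self, plus_gene):
        with pytest.raises(ValueError):
            classify_tss(-5, "-", [plus_gene])
        with pytest.raises(ValueError):
            classify_tss(5000, "-", [plus_gene], replicon_length=3000)


def brute_force_caller(plus, minus, params):
    """Naive reference: test every position, then group left to right."""
    from scipy.stats import poisson

    cands = [i for i in range(len(plus))
             if plus[i] >= params.min_reads
             and poisson.sf(plus[i] - 1, max(minus[i], 1)) < params.p_max]
    groups = []
    for pos in cands:
        if groups and pos - groups[-1][-1] <= params.cluster_nt:
            groups[-1].append(pos)
        else:
            groups.append([pos])
    reps = []
    for grp in groups:
        best = max(plus[p] for p in grp)
        reps.append(min(p for p in grp if plus[p] == best))
    return reps


class TestCaller:
    def _tracks(self, plus_vals, minus_vals=None, n=1000):
        plus = np.zeros(n, dtype=np.int64)
        for pos, v in plus_vals.items():
            plus[pos] = v
        minus = np.zeros(n, dtype=np.int64)
        for pos, v in (minus_vals or {}).items():
            minus[pos] = v
        return (make_track(plus, kind="five_prime", lib="tex_plus"),
                make_track(minus, kind="five_prime", lib="tex_minus"))

    def test_clear_enrichment_called(self):
        sites = call_tss(*self._tracks({500: 10}))
        assert [s.position for s in sites] == [500]

    def test_min_reads_threshold(self):
        assert call_tss(*self._tracks({500: 3})) == []

    def test_cluster_representative_is_max_count(self):
        sites = call_tss(*self._tracks({500: 9, 503: 12}))
        assert [s.position for s in sites] == [503]

    def test_tex_minus_background_suppresses(self):
        # 10 reads over a background of 10: not enriched
        sites = call_tss(*self._tracks({500: 10}, {500: 10}))
        assert sites == []

    def test_mismatched_tracks_rejected(self):
        plus, minus = self._tracks({500: 10})
        minus.strand = "-"
        with pytest.raises(ValueError):
            call_tss(plus, minus)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.dictionaries(st.integers(0, 199), st.integers(0, 30),
                           max_size=25))
    def test_agrees_with_naive_grouping(self, counts):
        params = TssCallerParams()
        plus, minus = self._tracks(counts, n=200)
        got = [s.position for s in call_tss(plus, minus, params)]
        assert got == brute_force_caller(plus.values, minus.values, params)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.dictionaries(st.integers(0, 199), st.integers(0, 30), max_size=15),
           st.integers(1, 20))
    def test_boosting_an_isolated_site_never_removes_it(self, counts, boost):
        """Raising the TEX+ count of a reported site that has no other
        candidate nearby keeps that site in the output."""
        params = TssCallerParams()
        plus, minus = self._tracks(counts, n=200)
        before = call_tss(plus, minus, params)
        isolated = [
            s.position for s in before
            if not any(plus.values[q] >= params.min_reads
                       and q != s.position
                       for q in range(max(0, s.position - 2 * params.cluster_nt),
                                      min(200, s.position + 2 * params.cluster_nt + 1)))
        ]
        if not isolated:
            return
        pos = isolated[0]
        plus.values[pos] += boost
        after = call_tss(plus, minus, params)
        assert pos in [s.position for s in after]
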