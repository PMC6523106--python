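"""TSS classification relative to the gene annotation, and an optional
simplified dRNA-seq TSS caller.

A TSS inside a gene on the opposite strand is antisense (aTSS). A TSS on
the opposite strand within 200 nt past a gene's 3' end — measured in the
gene's orientation — and not inside any opposite-strand gene is downstream
antisense (daTSS). The classes are disjoint and antisense takes
precedence: a site inside one gene and downstream of another is an aTSS.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .model import (ANTISENSE, DOWNSTREAM_ANTISENSE, OTHER, Gene,
                    ProfileTrack, Tss, TssCallerParams, opposite_strand)

logger = logging.getLogger(__name__)


class GeneIndex:
    """Per-replicon, per-strand interval lookup over a gene set.

    Genes in a prokaryotic annotation rarely nest, so a sorted-start array
    with a bounded back-scan (by maximum gene length) is adequate and keeps
    lookups O(log n + overlap).
    """

    def __init__(self, genes: Iterable[Gene]):
        self._by_key: dict[tuple[str, str], tuple[list[int], list[Gene]]] = {}
        buckets: dict[tuple[str, str], list[Gene]] = {}
        for g in genes:
            buckets.setdefault((g.replicon, g.strand), []).append(g)
        self._max_len: dict[tuple[str, str], int] = {}
        for key, gs in buckets.items():
            gs.sort(key=lambda g: (g.start, g.end, g.locus_tag))
            self._by_key[key] = ([g.start for g in gs], gs)
            self._max_len[key] = max(len(g) for g in gs)

    def overlapping(self, replicon: str, strand: str, start: int, end: int) -> list[Gene]:
        """Genes on (replicon, strand) intersecting [start, end)."""
        key = (replicon, strand)
        if key not in self._by_key:
            return []
        starts, gs = self._by_key[key]
        lo = bisect_right(starts, start - self._max_len[key])
        hi = bisect_right(starts, end - 1)
        return [g for g in gs[lo:hi] if g.start < end and start < g.end]

    def containing(self, replicon: str, strand: str, position: int) -> list[Gene]:
        return self.overlapping(replicon, strand, position, position + 1)


def downstream_window_of(gene: Gene, da_window_nt: int) -> tuple[int, int]:
    """Half-open interval covering up to ``da_window_nt`` nt past the
    gene's 3' end, in gene orientation."""
    if gene.strand == "+":
        return gene.end, gene.end + da_window_nt
    return gene.start - da_window_nt, gene.start


def classify_tss(position: int, strand: str, genes: GeneIndex | Iterable[Gene],
                 da_window_nt: int = 200,
                 replicon: str | None = None,
                 replicon_length: int | None = None) -> tuple[str, list[Gene]]:
    """Classify one TSS as antisense / downstream_antisense / other.

    Returns the class and every qualifying gene (two entries mean the site
    is antisense to two overlapping genes). ``genes`` may be a prebuilt
    :class:`GeneIndex` or any iterable of genes (single-replicon use: the
    replicon defaults to the genes' replicon).
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(list(genes))
    if replicon is None:
        reps = {key[0] for key in index._by_key}
        if len(reps) != 1:
            raise ValueError("replicon must be named for multi-replicon annotations")
        replicon = reps.pop()
    if position < 0 or (replicon_length is not None and position >= replicon_length):
        raise ValueError(f"TSS position {position} outside replicon {replicon!r}")
    opp = opposite_strand(strand)
    inside = index.containing(replicon, opp, position)
    if inside:
        return ANTISENSE, sorted(inside, key=lambda g: (g.start, g.locus_tag))
    # any gene whose downstream window reaches `position` has its 3' end
    # within da_window_nt of it, so the gene body intersects this range
    nearby = index.overlapping(replicon, opp,
                               position - da_window_nt, position + da_window_nt + 1)
    downstream = [g for g in nearby if _in_downstream_window(g, position, da_window_nt)]
    if downstream:
        return DOWNSTREAM_ANTISENSE, sorted(downstream, key=lambda g: (g.start, g.locus_tag))
    return OTHER, []


def _in_downstream_window(gene: Gene, position: int, da_window_nt: int) -> bool:
    lo, hi = downstream_window_of(gene, da_window_nt)
    return lo <= position < hi


def classify_all(sites: Iterable[Tss], genes: Iterable[Gene] | GeneIndex,
                 da_window_nt: int = 200) -> list[Tss]:
    """Classify a set of TSS in place (class + cognate gene tags) and
    return them. Ids are preserved; class-wise renumbering is a separate
    step (:func:`number_sites`)."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(list(genes))
    out = []
    for t in sites:
        cls, cognate = classify_tss(t.position, t.strand, index, da_window_nt,
                                    replicon=t.replicon)
        t.tss_class = cls
        t.cognate_genes = [g.locus_tag for g in cognate]
        out.append(t)
    return out


def number_sites(sites: Sequence[Tss]) -> None:
    """Assign ``aTSS_<n>`` / ``daTSS_<n>`` ids by genomic order within each
    class (1-based ordinals), leaving ``other`` sites' ids untouched."""
    counters = {ANTISENSE: 0, DOWNSTREAM_ANTISENSE: 0}
    prefix = {ANTISENSE: "aTSS", DOWNSTREAM_ANTISENSE: "daTSS"}
    for t in sorted(sites, key=lambda t: (t.replicon, t.position, t.strand)):
        if t.tss_class in counters:
            counters[t.tss_class] += 1
            t.id = f"{prefix[t.tss_class]}_{counters[t.tss_class]}"


# ---------------------------------------------------------------------------
# Simplified TSS caller

def call_tss(tex_plus_5p: ProfileTrack, tex_minus_5p: ProfileTrack,
             params: TssCallerParams | None = None) -> list[Tss]:
    """Call TSS positions from TEX+/TEX- 5'-end accumulation profiles.

    A position is a candidate when its TEX+ 5'-end count is at least
    ``min_reads`` and a one-sided Poisson test of that count against a mean
    of max(TEX- count, 1) gives p < ``p_max``. Candidates closer than
    ``cluster_nt`` are grouped; the position with the maximal TEX+ count
    (leftmost on ties) represents each group.

    This is a deliberately simple enrichment test standing in for a full
    dRNA-seq caller; it shares the latter's parameter surface (p < 0.005,
    >= 4 reads, 5 nt grouping) but not its statistical model.
    """
    if params is None:
        params = TssCallerParams()
    if (tex_plus_5p.replicon != tex_minus_5p.replicon
            or tex_plus_5p.strand != tex_minus_5p.strand):
        raise ValueError("TEX+ and TEX- tracks must share replicon and strand")
    if len(tex_plus_5p) != len(tex_minus_5p):
        raise ValueError("TEX+ and TEX- tracks must have equal length")
    plus = tex_plus_5p.values
    minus = tex_minus_5p.values
    candidates = np.flatnonzero(plus >= params.min_reads)
    if candidates.size:
        lam = np.maximum(minus[candidates], 1)
        # P(X >= k | lambda) for k = observed TEX+ count
        pvals = stats.poisson.sf(plus[candidates] - 1, lam)
        candidates = candidates[pvals < params.p_max]
    sites: list[Tss] = []
    group: list[int] = []

    def flush(group: list[int]) -> None:
        if not group:
            return
        counts = plus[group]
        rep = group[int(np.argmax(counts))]  # argmax returns leftmost on ties
        sites.append(Tss(id=f"TSS_{rep}", replicon=tex_plus_5p.replicon,
                         position=int(rep), strand=tex_plus_5p.strand,
                         read_support=int(plus[rep])))

    for pos in candidates:
        if group and pos - group[-1] > params.cluster_nt:
            flush(group)
            group = []
        group.append(int(pos))
    flush(group)
    logger.info("call_tss: %d candidate positions -> %d sites on %s(%s)",
                len(candidates), len(sites), tex_plus_5p.replicon,
                tex_plus_5p.strand)
    return sites
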